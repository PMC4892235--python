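"""End-to-end audit on a synthetic scenario.

Generates a tree + taxonomy + clustered scored-tip bundle on disk, runs the
full audit (coverage at three levels plus dispersion tests), and prints the
report table the way a real analysis would.
"""

import tempfile
from pathlib import Path

from morphaudit import (AuditConfig, generate_scenario, run_audit,
                        summarize_counts, write_scenario)

workdir = Path(tempfile.mkdtemp(prefix="morphaudit_"))
scenario = generate_scenario(n_tips=64, coverage=0.25, regime="clustered", seed=11)
paths = write_scenario(scenario, str(workdir / "scenario"))

config = AuditConfig(
    tree_path=paths["tree"],
    taxonomy_path=paths["taxonomy"],
    scored_paths=[paths["scored"]],
    reps=1000,
    seed=11,
    out_tsv=str(workdir / "report.tsv"),
    annotate_out=str(workdir / "annotated.nwk"),
)
report = run_audit(config)
print(report.to_tsv())
print("coverage-class tallies over orders:")
print(summarize_counts(report).to_string())
print(f"\nreport and annotated tree written under {workdir}")

print("""
Reading: the scored tips were drawn as one tight phylogenetic neighbourhood
(clustered regime), so the species-level rows show strongly positive
NRI/NTI with small randomization p-values (stars: * p<0.05, ** p<0.01).
The 'Mammalia' rows pool all orders; the order rows use the order-pruned
tree.""")
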