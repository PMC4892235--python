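"""Orchestration: run the full coverage + dispersion audit over every clade
and taxonomic level, and emit the tabular report.

The report has one row per (clade, level) plus class-wide rows, mirroring
the shape of a per-order summary table: counts, coverage proportion and
class, NRI/NTI with randomization p-values and significance stars.
Class-wide dispersion uses the full tree as the sampling pool; each order's
uses the order-pruned tree.  Genus- and family-level dispersion collapses
the species tree to one exemplar tip per group (see docs/methods.md).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import dendropy
import pandas as pd

from .coverage import (LEVELS, TaxonomyTable, FocalSet, CoverageRecord,
                       classify_coverage, coverage as coverage_of,
                       filter_to_reference, lift_to_level, normalize_name,
                       read_scored_names)
from .dispersion import DispersionResult, dispersion_test
from .tree_io import DistanceMatrix, patristic_matrix, read_tree, tip_labels

logger = logging.getLogger(__name__)

LEVEL_ORDER = ("family", "genus", "species")

REPORT_COLUMNS = [
    "clade", "level", "n_scored", "n_total", "proportion", "coverage_class",
    "nri", "p_nri", "sig_nri", "nti", "p_nti", "sig_nti",
]


@dataclass
class AuditConfig:
    """Everything one audit run needs; a fixed config + seed byte-reproduces
    the report."""

    tree_path: str
    taxonomy_path: str
    scored_paths: Sequence[str]
    levels: Sequence[str] = LEVEL_ORDER
    clade_column: str = "order"
    class_label: str = "Mammalia"
    reps: int = 1000
    seed: int = 0
    low: float = 0.25
    high: float = 0.75
    underscores_to_spaces: bool = True
    out_tsv: str | None = None
    annotate_out: str | None = None
    audit_json: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError("low threshold must be below high threshold")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        unknown = set(self.levels) - set(LEVELS)
        if unknown:
            raise ValueError(f"unknown levels: {sorted(unknown)}")


@dataclass
class AuditReport:
    """Combined coverage + dispersion rows, one per clade x level."""

    rows: pd.DataFrame
    config: AuditConfig
    results: list = field(default_factory=list, repr=False)

    def to_tsv(self, path: str | None = None) -> str:
        """Fixed-format TSV: proportions to 4 decimals, indices to 2,
        p-values to 4, NA for untested cells; byte-stable under a seed."""
        df = self.rows.copy()

        def fmt(x, nd):
            return "NA" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.{nd}f}"

        df["proportion"] = [fmt(x, 4) for x in df["proportion"]]
        for c in ("nri", "nti"):
            df[c] = [fmt(x, 2) for x in df[c]]
        for c in ("p_nri", "p_nti"):
            df[c] = [fmt(x, 4) for x in df[c]]
        text = df[REPORT_COLUMNS].to_csv(sep="\t", index=False)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def significance_stars(p: float) -> str:
    """'**' for p<0.01, '*' for p<0.05, '' otherwise (or for NA)."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _level_matrix(species_dm: DistanceMatrix, taxonomy: TaxonomyTable,
                  level: str) -> DistanceMatrix:
    """Collapse a species distance matrix to one exemplar per genus/family.

    The exemplar is the alphabetically first in-tree species of each group;
    rows are relabeled with the group names.
    """
    if level == "species":
        return species_dm
    group_of = (taxonomy.genus_of if level == "genus" else taxonomy.family_of)
    exemplar: dict[str, str] = {}
    for sp in sorted(species_dm.labels):
        g = group_of(sp)
        exemplar.setdefault(g, sp)
    sub = species_dm.submatrix(exemplar.values())
    return sub.relabel({sp: g for g, sp in exemplar.items()})


def _row(covrec: CoverageRecord, disp: DispersionResult) -> dict:
    return {
        "clade": covrec.clade, "level": covrec.level,
        "n_scored": covrec.n_scored, "n_total": covrec.n_total,
        "proportion": covrec.proportion, "coverage_class": covrec.klass,
        "nri": disp.nri, "p_nri": disp.p_nri, "sig_nri": significance_stars(disp.p_nri),
        "nti": disp.nti, "p_nti": disp.p_nti, "sig_nti": significance_stars(disp.p_nti),
    }


def run_audit(config: AuditConfig) -> AuditReport:
    """Run the full audit described by ``config``.

    Reads and normalizes the tree, taxonomy and scored-OTU lists, then for
    the class-wide pool and every order computes the coverage record and —
    whenever 2 <= n focal tips < pool size — the dispersion test at each
    requested level.  Deterministic for a fixed seed.
    """
    handler = None
    if config.log_path:
        handler = logging.FileHandler(config.log_path, mode="w")
        handler.setLevel(logging.INFO)
        pkg_logger = logging.getLogger("morphaudit")
        pkg_logger.addHandler(handler)
        pkg_logger.setLevel(logging.INFO)
    try:
        return _run_audit(config)
    finally:
        if handler is not None:
            logging.getLogger("morphaudit").removeHandler(handler)
            handler.close()


def _run_audit(config: AuditConfig) -> AuditReport:
    logger.info("audit start: seed=%d reps=%d", config.seed, config.reps)
    tree = read_tree(config.tree_path,
                     underscores_to_spaces=config.underscores_to_spaces)
    taxonomy = TaxonomyTable.from_csv(config.taxonomy_path)
    taxonomy = TaxonomyTable(taxonomy.df.assign(
        species=[normalize_name(s) for s in taxonomy.df["species"]]))

    # normalize tree tip labels in place so tree/taxonomy/matrix names agree
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_name(leaf.taxon.label)

    raw_names: list[str] = []
    for path in config.scored_paths:
        names = read_scored_names(path)
        logger.info("read %d OTU name(s) from %s", len(names), path)
        raw_names.extend(names)
    scored = {normalize_name(n) for n in raw_names}
    known = taxonomy.species | taxonomy.genera | taxonomy.families
    scored = filter_to_reference(scored, known)
    logger.info("%d unique scored name(s) after normalization and filtering", len(scored))

    tips = tip_labels(tree)
    tree_species = sorted(tips & taxonomy.species)
    dropped_tips = tips - taxonomy.species
    if dropped_tips:
        logger.info("%d tree tip(s) absent from taxonomy ignored for dispersion: %s",
                    len(dropped_tips), ", ".join(sorted(dropped_tips)))
    full_dm = patristic_matrix(tree).submatrix(tree_species) if len(tree_species) >= 2 else None

    rows, results = [], []
    clades = [config.class_label] + taxonomy.orders
    for clade in clades:
        is_class = clade == config.class_label
        clade_filter = None if is_class else clade
        if full_dm is not None:
            clade_species = [sp for sp in full_dm.labels
                             if is_class or taxonomy.order_of(sp) == clade]
            clade_dm = full_dm if is_class else (
                full_dm.submatrix(clade_species) if len(clade_species) >= 2 else None)
        else:
            clade_dm = None
        for level in config.levels:
            reference = taxonomy.reference_at(level, clade_filter)
            scored_level = lift_to_level(scored, taxonomy, level) & reference
            focal = FocalSet(clade, level, frozenset(scored_level), frozenset(reference))
            covrec = coverage_of(focal, low=config.low, high=config.high)
            if clade_dm is not None:
                level_dm = _level_matrix(clade_dm, taxonomy, level)
                disp = dispersion_test(level_dm, scored_level, reps=config.reps,
                                       seed=config.seed, clade=clade, level=level)
            else:
                nan = float("nan")
                disp = DispersionResult(clade, level, len(scored_level), nan, nan,
                                        nan, nan, nan, nan, config.reps, config.seed,
                                        reason="clade has fewer than 2 tips in tree")
                logger.info("dispersion %s/%s: %s", clade, level, disp.reason)
            rows.append(_row(covrec, disp))
            results.append((covrec, disp))

    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    report = AuditReport(df, config, results)
    if config.out_tsv:
        report.to_tsv(config.out_tsv)
        logger.info("report written to %s", config.out_tsv)
    if config.annotate_out:
        scored_tips = lift_to_level(scored, taxonomy, "species") & tips
        with open(config.annotate_out, "w") as fh:
            fh.write(annotate_tree(tree, scored_tips))
        logger.info("annotated tree written to %s", config.annotate_out)
    if config.audit_json:
        _dump_audit_json(report, config.audit_json)
    return report


def _dump_audit_json(report: AuditReport, path: str) -> None:
    """Full-precision dump of every record for audit trails."""
    payload = []
    for covrec, disp in report.results:
        entry = asdict(covrec)
        entry.update({k: (None if isinstance(v, float) and math.isnan(v) else v)
                      for k, v in asdict(disp).items() if k not in ("clade", "level")})
        payload.append(entry)
    with open(path, "w") as fh:
        json.dump({"config": {k: list(v) if isinstance(v, tuple) else v
                              for k, v in asdict(report.config).items()},
                   "records": payload}, fh, indent=2)
        fh.write("\n")


def summarize_counts(report: AuditReport | pd.DataFrame,
                     class_label: str = "Mammalia") -> pd.DataFrame:
    """Per-level tallies of low/medium/high coverage over the order rows
    (class-wide rows excluded)."""
    df = report.rows if isinstance(report, AuditReport) else report
    df = df[df["clade"] != class_label]
    out = (df.groupby(["level", "coverage_class"]).size()
             .unstack(fill_value=0)
             .reindex(columns=["low", "medium", "high"], fill_value=0))
    out.columns.name = None
    return out


def coverage_report_from_counts(counts: pd.DataFrame, *, low: float = 0.25,
                                high: float = 0.75) -> pd.DataFrame:
    """Coverage-only report rows from printed (clade, level, n_scored,
    n_total) counts — no tree or name resolution involved."""
    rows = []
    for rec in counts.itertuples(index=False):
        p = rec.n_scored / rec.n_total
        rows.append({"clade": rec.clade, "level": rec.level,
                     "n_scored": int(rec.n_scored), "n_total": int(rec.n_total),
                     "proportion": p, "coverage_class": classify_coverage(p, low=low, high=high)})
    return pd.DataFrame(rows)


def annotate_tree(tree: dendropy.Tree, scored: Iterable[str]) -> str:
    """Newick string with a binary ``[&scored=0|1]`` annotation on each tip.

    Downstream plotting can highlight scored tip branches from this alone.
    """
    scored = set(scored)
    extra = scored - tip_labels(tree)
    if extra:
        raise ValueError(f"scored names not in tree: {sorted(extra)}")
    annotated = tree.clone(depth=1)
    for leaf in annotated.leaf_node_iter():
        leaf.annotations.add_new("scored", 1 if leaf.taxon.label in scored else 0)
    return annotated.as_string(schema="newick", suppress_annotations=False,
                               suppress_rooting=True)
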