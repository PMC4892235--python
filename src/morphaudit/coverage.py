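"""Taxonomic coverage of scored taxa: name normalization, level lifting,
per-clade coverage records and the low/medium/high classification.

A "scored" taxon is one with at least one coded character available in some
public discrete morphological matrix.  Coverage of a clade at a taxonomic
level is the fraction of that clade's taxa (species, genera or families)
that are scored.  A clade has *low* coverage when strictly less than 25% of
its taxa are scored and *high* coverage when strictly more than 75% are;
exact boundary values are medium.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LEVELS = ("species", "genus", "family")

#: Regexes stripped (in order) from a raw OTU name before tokenizing.
#: They remove authority strings, years, and open-nomenclature / matrix-rank
#: markers such as "sp.", "cf." or "indet." that morphological matrices
#: commonly append to taxon labels.
DEFAULT_STRIP_PATTERNS = (
    r"\([^)]*\)",                       # parenthetical (authority, remarks)
    r",.*$",                            # everything after a comma
    r"\b(?:1[6-9]\d{2}|20\d{2})[a-z]?\b.*$",  # year token and trailing text
    r"\b(?:sp|spp|cf|aff|indet|gen|nov)\.?(?=\s|$).*$",
)


class NameError_(ValueError):
    """Raised when a taxon name is empty after cleaning."""


def normalize_name(raw: str, strip_patterns: Sequence[str] = DEFAULT_STRIP_PATTERNS) -> str:
    """Canonicalize a taxon name to ``"Genus"`` or ``"Genus epithet"``.

    Underscores become spaces, whitespace is collapsed, configurable
    regexes strip authority/year/rank suffixes, the genus is capitalized and
    the epithet lower-cased.  Tokens beyond the binomial (subspecies,
    trailing authors) are dropped.  Idempotent by construction.
    """
    s = raw.replace("_", " ").strip().strip("'\"")
    for pat in strip_patterns:
        s = re.sub(pat, " ", s)
    tokens = [t for t in s.split() if t]
    if not tokens:
        raise NameError_(f"name {raw!r} is empty after cleaning")
    genus = tokens[0].capitalize()
    if len(tokens) >= 2 and tokens[1].isalpha():
        return f"{genus} {tokens[1].lower()}"
    return genus


def filter_to_reference(scored: Iterable[str], reference: Iterable[str]) -> set[str]:
    """Intersect scored names with a reference set, logging exclusions.

    Mirrors the audit's exclusion step: names absent from the reference
    phylogeny/taxonomy (fossils, synonyms that failed to resolve) are
    dropped with an audit trail.
    """
    scored, reference = set(scored), set(reference)
    excluded = scored - reference
    if excluded:
        logger.info(
            "excluded %d name(s) not in reference: %s",
            len(excluded), ", ".join(sorted(excluded)),
        )
    return scored & reference


class TaxonomyTable:
    """Species → genus → family → order mapping.

    Wraps a DataFrame with columns ``species, genus, family, order``;
    species are unique and every rank entry is non-empty.
    """

    COLUMNS = ("species", "genus", "family", "order")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"taxonomy missing columns: {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].astype(str).apply(lambda c: c.str.strip())
        if df["species"].duplicated().any():
            dups = df["species"][df["species"].duplicated()].tolist()
            raise ValueError(f"duplicate species in taxonomy: {dups}")
        if (df == "").any().any():
            raise ValueError("taxonomy contains empty fields")
        self.df = df.reset_index(drop=True)
        self._genus_of = dict(zip(df["species"], df["genus"]))
        self._family_of_species = dict(zip(df["species"], df["family"]))
        self._family_of_genus = dict(zip(df["genus"], df["family"]))
        self._order_of_species = dict(zip(df["species"], df["order"]))

    @classmethod
    def from_csv(cls, path: str) -> "TaxonomyTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    @property
    def species(self) -> set[str]:
        return set(self._genus_of)

    @property
    def genera(self) -> set[str]:
        return set(self._family_of_genus)

    @property
    def families(self) -> set[str]:
        return set(self.df["family"])

    @property
    def orders(self) -> list[str]:
        return sorted(self.df["order"].unique())

    def genus_of(self, species: str) -> str:
        return self._genus_of[species]

    def family_of(self, name: str) -> str:
        """Family of a species (binomial) or genus (single-token) name."""
        if name in self._family_of_species:
            return self._family_of_species[name]
        return self._family_of_genus[name]

    def order_of(self, species: str) -> str:
        return self._order_of_species[species]

    def reference_at(self, level: str, clade: str | None = None) -> set[str]:
        """All taxon names at ``level`` (optionally within one order)."""
        if level not in LEVELS:
            raise ValueError(f"unknown level {level!r}")
        df = self.df if clade is None else self.df[self.df["order"] == clade]
        return set(df[level])


def lift_to_level(names: Iterable[str], taxonomy: TaxonomyTable, level: str,
                  *, strict: bool = False) -> set[str]:
    """Project a set of scored OTU names onto one taxonomic level.

    Species-rank names (binomials) lift to their genus or family; names
    already at genus rank certify the genus and its family but *no*
    particular species, so they are dropped at species level.  Family-rank
    names count only at family level.  Names that resolve nowhere in the
    taxonomy are dropped with a log entry (or raise under ``strict``).
    """
    if level not in LEVELS:
        raise ValueError(f"unknown level {level!r}")
    out: set[str] = set()
    unresolved: list[str] = []
    for name in names:
        if name in taxonomy.species:
            if level == "species":
                out.add(name)
            elif level == "genus":
                out.add(taxonomy.genus_of(name))
            else:
                out.add(taxonomy.family_of(name))
        elif name in taxonomy.genera:
            if level == "genus":
                out.add(name)
            elif level == "family":
                out.add(taxonomy.family_of(name))
        elif name in taxonomy.families:
            if level == "family":
                out.add(name)
        else:
            unresolved.append(name)
    if unresolved:
        if strict:
            raise ValueError(f"names not resolvable in taxonomy: {sorted(unresolved)}")
        logger.info("dropped %d unresolvable name(s): %s",
                    len(unresolved), ", ".join(sorted(unresolved)))
    return out


@dataclass(frozen=True)
class FocalSet:
    """The scored taxa at one taxonomic level within one clade."""

    clade: str
    level: str
    scored: frozenset[str]
    reference: frozenset[str]

    def __post_init__(self):
        if not self.scored <= self.reference:
            extra = sorted(self.scored - self.reference)
            raise ValueError(f"scored names outside reference: {extra}")


@dataclass(frozen=True)
class CoverageRecord:
    clade: str
    level: str
    n_scored: int
    n_total: int
    proportion: float
    klass: str


def classify_coverage(p: float, *, low: float = 0.25, high: float = 0.75) -> str:
    """low / medium / high coverage class for a scored proportion ``p``.

    Boundaries are strict: exactly ``low`` or exactly ``high`` is medium.
    """
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if p < low:
        return "low"
    if p > high:
        return "high"
    return "medium"


def coverage(focal: FocalSet, *, low: float = 0.25, high: float = 0.75) -> CoverageRecord:
    """Coverage record (counts, proportion, class) for one focal set."""
    n_total = len(focal.reference)
    if n_total < 1:
        raise ValueError(f"empty reference for {focal.clade}/{focal.level}")
    n_scored = len(focal.scored)
    p = n_scored / n_total
    return CoverageRecord(focal.clade, focal.level, n_scored, n_total, p,
                          classify_coverage(p, low=low, high=high))


# ---------------------------------------------------------------------------
# Scored-OTU list ingestion

_NEXUS_COMMENT = re.compile(r"\[[^\]]*\]")


def read_nexus_taxa(text: str) -> list[str]:
    """Extract taxon names from a NEXUS file's TAXLABELS or MATRIX block.

    Character states are never interpreted: the audit needs only which taxa
    are present.  Quoted labels keep internal spaces; unquoted underscores
    become spaces.
    """
    text = _NEXUS_COMMENT.sub(" ", text)
    m = re.search(r"\bTAXLABELS\b(.*?);", text, re.I | re.S)
    if m:
        return _nexus_tokens(m.group(1))
    m = re.search(r"\bMATRIX\b(.*?);", text, re.I | re.S)
    if m:
        names = []
        for line in m.group(1).splitlines():
            line = line.strip()
            if not line:
                continue
            tok = _nexus_tokens(line)
            if tok:
                names.append(tok[0])
        # interleaved matrices repeat names; keep first occurrence order
        seen, out = set(), []
        for n in names:
            if n not in seen:
                seen.add(n)
                out.append(n)
        return out
    raise ValueError("no TAXLABELS or MATRIX block found")


def _nexus_tokens(chunk: str) -> list[str]:
    toks = re.findall(r"'([^']*)'|\"([^\"]*)\"|(\S+)", chunk)
    return [a or b or c.replace("_", " ") for a, b, c in toks]


def read_scored_names(path: str) -> list[str]:
    """Raw OTU names from a NEXUS matrix or a one-name-per-line text file."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip()[:6].upper() == "#NEXUS":
        return read_nexus_taxa(text)
    return [ln.strip() for ln in text.splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")]
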