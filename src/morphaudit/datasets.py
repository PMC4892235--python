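"""Bundled reference counts for worked examples and checks.

``mammal_census()`` returns the published per-order counts of living mammal
taxa with at least one coded anatomical character available in public
discrete morphological matrices (pooled from 286 matrices), at three
taxonomic levels, together with the class-wide totals.  Each row is
(clade, level, n_scored, n_total).  These counts are the inputs to the
coverage arithmetic; no tree is involved.
"""

from __future__ import annotations

import pandas as pd

CLASS_LABEL = "Mammalia"

# (clade, level, n_scored, n_total); class-wide rows first, then the 28
# orders alphabetically with family/genus/species rows each.
MAMMAL_CENSUS: tuple[tuple[str, str, int, int], ...] = (
    ("Mammalia", "family", 129, 148),
    ("Mammalia", "genus", 517, 1186),
    ("Mammalia", "species", 847, 5017),
    ("Afrosoricida", "family", 2, 2),
    ("Afrosoricida", "genus", 17, 17),
    ("Afrosoricida", "species", 23, 42),
    ("Carnivora", "family", 14, 15),
    ("Carnivora", "genus", 52, 125),
    ("Carnivora", "species", 75, 283),
    ("Cetartiodactyla", "family", 21, 21),
    ("Cetartiodactyla", "genus", 97, 128),
    ("Cetartiodactyla", "species", 169, 310),
    ("Chiroptera", "family", 15, 18),
    ("Chiroptera", "genus", 92, 202),
    ("Chiroptera", "species", 214, 1053),
    ("Cingulata", "family", 1, 1),
    ("Cingulata", "genus", 8, 9),
    ("Cingulata", "species", 9, 29),
    ("Dasyuromorphia", "family", 2, 2),
    ("Dasyuromorphia", "genus", 8, 22),
    ("Dasyuromorphia", "species", 9, 64),
    ("Dermoptera", "family", 1, 1),
    ("Dermoptera", "genus", 1, 2),
    ("Dermoptera", "species", 1, 2),
    ("Didelphimorphia", "family", 1, 1),
    ("Didelphimorphia", "genus", 16, 16),
    ("Didelphimorphia", "species", 42, 84),
    ("Diprotodontia", "family", 11, 11),
    ("Diprotodontia", "genus", 25, 38),
    ("Diprotodontia", "species", 31, 126),
    ("Erinaceomorpha", "family", 1, 1),
    ("Erinaceomorpha", "genus", 10, 10),
    ("Erinaceomorpha", "species", 21, 22),
    ("Hyracoidea", "family", 1, 1),
    ("Hyracoidea", "genus", 1, 3),
    ("Hyracoidea", "species", 1, 4),
    ("Lagomorpha", "family", 2, 2),
    ("Lagomorpha", "genus", 5, 12),
    ("Lagomorpha", "species", 12, 86),
    ("Macroscelidea", "family", 1, 1),
    ("Macroscelidea", "genus", 4, 4),
    ("Macroscelidea", "species", 12, 15),
    ("Microbiotheria", "family", 1, 1),
    ("Microbiotheria", "genus", 1, 1),
    ("Microbiotheria", "species", 1, 1),
    ("Monotremata", "family", 2, 2),
    ("Monotremata", "genus", 2, 3),
    ("Monotremata", "species", 2, 4),
    ("Notoryctemorphia", "family", 1, 1),
    ("Notoryctemorphia", "genus", 1, 1),
    ("Notoryctemorphia", "species", 0, 2),
    ("Paucituberculata", "family", 1, 1),
    ("Paucituberculata", "genus", 3, 3),
    ("Paucituberculata", "species", 5, 5),
    ("Peramelemorphia", "family", 2, 2),
    ("Peramelemorphia", "genus", 7, 7),
    ("Peramelemorphia", "species", 16, 18),
    ("Perissodactyla", "family", 3, 3),
    ("Perissodactyla", "genus", 6, 6),
    ("Perissodactyla", "species", 10, 16),
    ("Pholidota", "family", 1, 1),
    ("Pholidota", "genus", 1, 1),
    ("Pholidota", "species", 4, 8),
    ("Pilosa", "family", 4, 5),
    ("Pilosa", "genus", 4, 5),
    ("Pilosa", "species", 5, 29),
    ("Primates", "family", 15, 15),
    ("Primates", "genus", 48, 68),
    ("Primates", "species", 64, 351),
    ("Proboscidea", "family", 1, 1),
    ("Proboscidea", "genus", 2, 2),
    ("Proboscidea", "species", 2, 3),
    ("Rodentia", "family", 18, 32),
    ("Rodentia", "genus", 82, 450),
    ("Rodentia", "species", 90, 2094),
    ("Scandentia", "family", 2, 2),
    ("Scandentia", "genus", 2, 5),
    ("Scandentia", "species", 3, 20),
    ("Sirenia", "family", 2, 2),
    ("Sirenia", "genus", 2, 2),
    ("Sirenia", "species", 4, 4),
    ("Soricomorpha", "family", 3, 4),
    ("Soricomorpha", "genus", 19, 43),
    ("Soricomorpha", "species", 21, 392),
    ("Tubulidentata", "family", 1, 1),
    ("Tubulidentata", "genus", 1, 1),
    ("Tubulidentata", "species", 1, 1),
)


def mammal_census(include_class_rows: bool = True) -> pd.DataFrame:
    """The census as a DataFrame with columns clade, level, n_scored, n_total."""
    df = pd.DataFrame(MAMMAL_CENSUS, columns=["clade", "level", "n_scored", "n_total"])
    if not include_class_rows:
        df = df[df["clade"] != CLASS_LABEL].reset_index(drop=True)
    return df
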