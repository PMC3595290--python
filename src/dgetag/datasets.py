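"""Published reference tables bundled as analysis inputs.

Small printed tables from the *Volvariella volvacea* (straw mushroom)
genome/DGE study used throughout the examples and validation suite:

* the DGE library characteristics ledger for the two homokaryons
  (PYd21, PYd15) and their heterokaryon (H1521);
* the CAZyme class counts for 15 sequenced fungal genomes
  (8 basidiomycetes + 7 ascomycetes);
* the three-strain detection (Venn) summary;
* the worked heterokaryon-complementation example genes with their
  reported TPM values.

These are inputs transcribed from print, not values this package
computes.
"""

from __future__ import annotations

import pandas as pd

from dgetag.cazy import FamilyAbundanceMatrix
from dgetag.qc import QCAccounting, ledger_from_components

STRAINS = ("PYd21", "H1521", "PYd15")

#: printed removal-ledger inputs per strain:
#: raw distinct/total, N-containing distinct/total, adaptor distinct/total, copy-1
_LIBRARY_COMPONENTS = {
    "PYd21": (149096, 5997268, 4485, 7989, 185, 202, 38176),
    "H1521": (199222, 5838613, 10815, 34045, 125, 131, 102656),
    "PYd15": (200492, 5876147, 8115, 16612, 442, 518, 105163),
}

#: printed clean and copy-number-threshold rows, (distinct, total) per strain,
#: for cross-checking derived ledgers
PRINTED_LEDGER_ROWS = {
    "Clean Tag": {"PYd21": (106250, 5950901), "H1521": (85626, 5701781), "PYd15": (86772, 5753854)},
    "CopyNum >= 2": {"PYd21": (106250, 5950901), "H1521": (85626, 5701781), "PYd15": (86772, 5753854)},
    "CopyNum > 5": {"PYd21": (50796, 5773726), "H1521": (38241, 5566832), "PYd15": (38525, 5616866)},
    "CopyNum > 10": {"PYd21": (31336, 5627851), "H1521": (26167, 5475214), "PYd15": (26479, 5525603)},
    "CopyNum > 20": {"PYd21": (20261, 5466439), "H1521": (18146, 5358011), "PYd15": (18269, 5405543)},
    "CopyNum > 50": {"PYd21": (11261, 5179615), "H1521": (11094, 5130768), "PYd15": (11056, 5172985)},
    "CopyNum > 100": {"PYd21": (6792, 4861631), "H1521": (7347, 4862831), "PYd15": (7341, 4908306)},
}


def library_components() -> pd.DataFrame:
    """Printed raw/removal counts per strain (the ledger's input rows)."""
    cols = [
        "raw_distinct", "raw_total",
        "n_containing_distinct", "n_containing_total",
        "adaptor_distinct", "adaptor_total", "singletons",
    ]
    return pd.DataFrame.from_dict(_LIBRARY_COMPONENTS, orient="index", columns=cols)


def library_ledger(strain: str) -> QCAccounting:
    """Ledger for one strain derived arithmetically from the printed inputs."""
    return ledger_from_components(*_LIBRARY_COMPONENTS[strain])


#: reference-genome detection summary across the three strains
GENE_UNIVERSE = 11534  #: predicted gene models in the reference set
UNDETECTED_IN_ALL = 2747  #: genes with no tags in any strain
DETECTED_IN_ALL = 6188  #: genes with tags in all three strains

BASIDIOMYCETES = (
    "V. volvacea",
    "S. commune",
    "Ph. chrysosporium",
    "P. placenta",
    "C. cinerea",
    "L. bicolor",
    "C. neoformans",
    "U. maydis",
)
ASCOMYCETES = (
    "S. cerevisiae",
    "A. niger",
    "N. crassa",
    "T. melanosporum",
    "P. indica",
    "Pe. chrysogenum",
    "T. reesei",
)

_CAZY_CLASS_COUNTS = {
    #               GH   GT  PL  CE
    "V. volvacea": (191, 44, 19, 31),
    "S. commune": (240, 75, 16, 30),
    "Ph. chrysosporium": (181, 66, 4, 20),
    "P. placenta": (124, 51, 4, 13),
    "C. cinerea": (211, 71, 13, 54),
    "L. bicolor": (163, 88, 7, 20),
    "C. neoformans": (75, 64, 3, 8),
    "U. maydis": (101, 64, 1, 19),
    "S. cerevisiae": (46, 68, 0, 3),
    "A. niger": (256, 123, 8, 25),
    "N. crassa": (173, 76, 4, 23),
    "T. melanosporum": (91, 96, 3, 14),
    "P. indica": (225, 73, 16, 45),
    "Pe. chrysogenum": (223, 103, 9, 22),
    "T. reesei": (200, 103, 3, 16),
}


def cazyme_class_counts() -> FamilyAbundanceMatrix:
    """CAZyme class counts for 15 fungal genomes as an abundance matrix.

    The "families" here are the four classes themselves (GH, GT, PL,
    CE), which is the resolution the comparative table is printed at.
    """
    df = pd.DataFrame.from_dict(
        _CAZY_CLASS_COUNTS, orient="index", columns=["GH", "GT", "PL", "CE"]
    )
    return FamilyAbundanceMatrix(df)


#: worked complementation example genes: (panel, gene, tpm_PYd21, tpm_PYd15, tpm_H1521)
_COMPLEMENTATION_ROWS = [
    ("A", "GME11100_g", 0.01, 775.83, 48.93),
    ("A", "GME7340_g", 0.01, 774.44, 631.03),
    ("A", "GME9879_g", 0.01, 747.5, 1.23),
    ("A", "GME7343_g", 0.01, 313.88, 61.74),
    ("A", "GME1292_g", 0.01, 287.98, 112.42),
    ("A", "GME3772_g", 0.01, 124.96, 26.48),
    ("A", "GME2776_g", 0.01, 39.97, 7.72),
    ("A", "GME8956_g", 0.01, 37.54, 46.13),
    ("A", "GME3790_g", 0.01, 32.5, 19.82),
    ("B", "GME11940_g", 263.32, 0.01, 48.06),
    ("B", "GME4853_g", 256.6, 0.01, 8.94),
    ("B", "GME11748_g", 251.22, 0.01, 6.14),
    ("B", "GME4080_g", 179.97, 0.01, 3.16),
    ("B", "GME2612_g", 38.99, 0.01, 7.54),
    ("B", "GME2589_g", 38.48, 0.01, 2.46),
    ("B", "GME5445_g", 33.1, 0.01, 17.89),
    ("B", "GME1642_g", 15.29, 0.01, 21.92),
    ("B", "GME3065_g", 13.78, 0.01, 19.47),
    ("C", "GME3812_g", 0.01, 0.01, 3284.76),
    ("C", "GME8874_g", 0.01, 1.39, 98.04),
    ("C", "GME2797_g", 0.01, 5.21, 186.78),
    ("C", "GME2976_g", 0.01, 9.04, 71.03),
    ("C", "GME10337_g", 0.34, 0.35, 70.86),
    ("C", "GME3377_g", 0.5, 0.01, 53.49),
    ("C", "GME7327_g", 0.67, 2.26, 144.17),
    ("C", "GME10002_g", 0.67, 5.21, 67.0),
    ("C", "GME10343_g", 0.84, 8.52, 574.56),
    ("C", "GME2777_g", 1.01, 1.22, 66.3),
    ("C", "GME5253_g", 1.01, 3.65, 77.87),
    ("C", "GME1902_g", 1.01, 4.34, 142.94),
    ("C", "GME3357_g", 1.51, 1.22, 100.85),
    ("C", "GME502_g", 1.51, 10.6, 164.51),
    ("C", "GME3962_g", 2.18, 2.43, 72.08),
    ("C", "GME5044_g", 2.69, 8.52, 59.1),
    ("C", "GME8904_g", 2.69, 15.82, 85.06),
    ("C", "GME8105_g", 2.86, 6.26, 63.84),
    ("C", "GME6749_g", 3.19, 6.95, 60.51),
    ("C", "GME4417_g", 3.53, 1.39, 1157.53),
    ("C", "GME5967_g", 3.53, 2.26, 62.96),
    ("C", "GME5307_g", 3.86, 1.39, 80.5),
    ("C", "GME2317_g", 4.2, 9.21, 230.28),
    ("C", "GME6508_g", 9.58, 5.04, 51.74),
    ("C", "GME6820_g", 10.59, 19.81, 97.34),
    ("C", "GME7379_g", 11.09, 2.95, 2659.7),
    ("C", "GME5714_g", 11.26, 4.69, 126.1),
    ("C", "GME5639_g", 11.93, 5.21, 133.99),
    ("C", "GME8928_g", 15.12, 17.9, 75.42),
    ("C", "GME910_g", 18.99, 13.56, 136.1),
]


def complementation_examples() -> pd.DataFrame:
    """Reported complementation example genes with TPM in the three strains."""
    return pd.DataFrame(
        _COMPLEMENTATION_ROWS,
        columns=["panel", "gene", "tpm_PYd21", "tpm_PYd15", "tpm_H1521"],
    ).set_index("gene")
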