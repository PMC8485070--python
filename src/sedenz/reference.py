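"""Reference metadata for the assayed enzymes.

The twelve hydrolytic enzymes targeted by fluorogenic substrate proxies in
deep-sediment assays, grouped into three classes: peptidases (cleave peptide
bonds; AMC-linked substrates), glycosyl hydrolases (cleave glycosidic bonds;
MUB-linked substrates), and alkaline phosphatase (cleaves phosphomonoesters).
Ornithyl aminopeptidase has no formally assigned EC number ("na").
"""

from __future__ import annotations

import pandas as pd

ENZYME_CLASSES = ("peptidase", "glycosylase", "phosphatase")
FLUOROPHORES = ("AMC", "MUB")
TREATMENTS = ("live", "autoclaved")

_ENZYME_ROWS = [
    # enzyme, class, substrate, fluorophore, EC
    ("leucyl aminopeptidase", "peptidase", "L-Leucine-AMC", "AMC", "3.4.11.1"),
    ("arginyl aminopeptidase", "peptidase", "L-Arginine-AMC", "AMC", "3.4.11.6"),
    ("prolyl aminopeptidase", "peptidase", "L-Proline-AMC", "AMC", "3.4.11.5"),
    ("ornithyl aminopeptidase", "peptidase", "Ornithine-AMC", "AMC", "na"),
    ("gingipain", "peptidase", "Z-Phe-Arg-AMC", "AMC", "3.4.22.37"),
    ("clostripain", "peptidase", "Z-Phe-Val-Arg-AMC", "AMC", "3.4.22.8"),
    ("beta-xylosidase", "glycosylase", "MUB-beta-D-xylopyranoside", "MUB", "3.2.1.37"),
    ("beta-cellobiohydrolase", "glycosylase", "MUB-beta-D-cellobioside", "MUB", "3.2.1.91"),
    ("N-acetyl-beta-glucosaminidase", "glycosylase", "MUB-N-acetyl-beta-D-glucosaminide", "MUB", "3.2.1.52"),
    ("beta-glucosidase", "glycosylase", "MUB-beta-D-glucopyranoside", "MUB", "3.2.1.21"),
    ("alpha-glucosidase", "glycosylase", "MUB-alpha-D-glucopyranoside", "MUB", "3.2.1.20"),
    ("alkaline phosphatase", "phosphatase", "MUB-phosphate", "MUB", "3.1.3.1"),
]

#: Depth grid (mbsf) of the study layout used as the synthetic default; the
#: stratigraphic unconformity separating marine from lacustrine deposits sits
#: at ~51.7 mbsf, between the 48.22 and 54.95 samples.
DEFAULT_DEPTHS_MBSF = (4.50, 11.10, 17.60, 24.30, 30.90, 37.50, 43.15, 48.22,
                       54.95, 61.55, 77.92)

UNCONFORMITY_MBSF = 51.7


def enzyme_table() -> pd.DataFrame:
    """Return the enzyme reference table (enzyme, enzyme_class, substrate,
    fluorophore, ec) as a fresh DataFrame."""
    return pd.DataFrame(
        _ENZYME_ROWS,
        columns=["enzyme", "enzyme_class", "substrate", "fluorophore", "ec"],
    )
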