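"""Reference datasets for the IGHV Region II duplication locus.

Two small published reference tables are bundled as in-memory data, for
worked examples and regression tests of the analysis logic:

* the sperm-typing genotype panel — detectability calls (``+`` detected,
  ``ud`` undetectable, ``-`` unresolved) for the 17 sequence tags
  VHS429–VHS518 across the 12 haplotypes of six unrelated sperm donors;
* the gene-segment divergence table — per pair of closely related gene
  segments (allelic counterparts between two assemblies, or paralogous
  copies between repeat blocks) the printed lengths, difference count and
  percent difference, together with the printed length cell that the percent
  was computed from.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TAG_ORDER = [
    "VHS429", "VHS437", "VHS444", "VHS449", "VHS454", "VHS458", "VHS462",
    "VHS468", "VHS475", "VHS479", "VHS485", "VHS493", "VHS499", "VHS504",
    "VHS510", "VHS514", "VHS518",
]

DONORS = ["#002", "#12", "AB005", "AB027", "AC09", "D18"]

# per tag: 12 statuses in donor-major order (#002 H1, #002 H2, #12 H1, ...)
_PANEL = {
    "VHS429": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS437": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS444": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS449": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS454": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS458": "ud ud ud ud ud ud ud ud ud ud ud ud",
    "VHS462": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS468": "+  +  ud ud +  +  +  ud +  +  +  +",
    "VHS475": "+  +  ud ud +  +  +  ud +  +  ud +",
    "VHS479": "ud ud ud ud ud ud ud ud ud ud ud ud",
    "VHS485": "+  +  ud +  +  +  +  -  +  +  +  +",
    "VHS493": "+  +  ud +  +  +  +  -  +  +  +  +",
    "VHS499": "+  +  ud +  +  +  +  -  +  +  +  +",
    "VHS504": "ud ud ud ud ud ud ud ud ud ud ud ud",
    "VHS510": "+  +  ud +  +  +  +  +  +  +  +  +",
    "VHS514": "+  +  +  +  +  +  +  +  +  +  +  +",
    "VHS518": "+  +  +  +  +  +  +  +  +  +  +  +",
}


def sperm_panel() -> pd.DataFrame:
    """The reference genotype panel: tags × (donor, haplotype) statuses."""
    columns = pd.MultiIndex.from_product([DONORS, ["H1", "H2"]],
                                         names=["donor", "haplotype"])
    rows = {t: _PANEL[t].split() for t in TAG_ORDER}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    df.index.name = "tag"
    return df


def sperm_panel_calls() -> list:
    """The panel as one :class:`~ighvdup.assay.HaplotypeCall` per column."""
    from .assay import HaplotypeCall

    df = sperm_panel()
    return [
        HaplotypeCall(donor=d, label=h, statuses=df[(d, h)].to_dict())
        for d, h in df.columns
    ]


@dataclass(frozen=True)
class DivergenceRow:
    """One printed divergence-table row.

    ``denominator`` is the printed length cell that reproduces the printed
    percent (the second segment's length, except the two repeat-vs-repeat
    rows marked ``denominator_side='len_a'``).
    """

    group: str
    name_a: str
    len_a: int
    name_b: str
    len_b: int
    diff: int
    percent: float
    denominator_side: str = "len_b"

    @property
    def denominator(self) -> int:
        return self.len_a if self.denominator_side == "len_a" else self.len_b


DIVERGENCE_ROWS: tuple[DivergenceRow, ...] = (
    # allelic counterparts between the two assemblies
    DivergenceRow("allelic", "4-28.1P", 253, "4-28.2P", 255, 2, 0.78),
    DivergenceRow("allelic", "3-29P", 458, "3-29.1P", 458, 6, 1.31),
    DivergenceRow("allelic", "3-30", 454, "3-30.1", 454, 1, 0.22),
    DivergenceRow("allelic", "4-31", 438, "4-28.1a", 438, 19, 4.34),
    DivergenceRow("allelic", "4-31", 438, "4-31.1", 438, 8, 1.83),
    DivergenceRow("allelic", "3-33", 454, "3-33.1", 202, 3, 1.49),
    # paralogous copies between repeat blocks of the reference assembly
    DivergenceRow("paralogous_ref", "4-28", 435, "4-31", 438, 29, 6.62),
    DivergenceRow("paralogous_ref", "4-28.1P", 253, "4-31.1P", 255, 12, 4.71),
    DivergenceRow("paralogous_ref", "3-29P", 458, "3-32P", 458, 13, 2.84),
    DivergenceRow("paralogous_ref", "3-30", 454, "3-33", 454, 4, 0.88),
    DivergenceRow("paralogous_ref", "4-30.1P", 274, "4-33.1", 274, 5, 1.82),
    DivergenceRow("paralogous_ref", "3-30.2P", 449, "3-33.2P", 449, 8, 1.78),
    DivergenceRow("paralogous_ref", "4-28", 438, "4-34", 433, 41, 9.36, "len_a"),
    DivergenceRow("paralogous_ref", "4-31", 438, "4-34", 433, 43, 9.82, "len_a"),
    # paralogous copies in the alternative (single-donor) assembly
    DivergenceRow("paralogous_alt", "4-28", 435, "4-28.1a", 438, 28, 6.39),
    DivergenceRow("paralogous_alt", "4-28", 435, "4-31.1", 438, 15, 3.42),
    DivergenceRow("paralogous_alt", "4-28.1a", 438, "4-31.1", 438, 17, 3.88),
    DivergenceRow("paralogous_alt", "3-30.1", 454, "3-33.1", 202, 3, 1.49),
    DivergenceRow("paralogous_alt", "4-28.1a", 438, "4-34", 433, 43, 9.93),
    DivergenceRow("paralogous_alt", "4-31.1", 438, "4-34", 433, 41, 9.47),
)

#: pooled allelic summary as printed: total difference, total length, percent
ALLELIC_POOLED = (39, 2245, 1.74)

#: pairwise divergence of the two complete repeat copies (excluding a private
#: transposon insertion), used by the clock's headline dating
REPEAT_DIVERGENCE = 0.0436

#: genomic average divergence: one substitution per 1,200 bp
GENOMIC_AVERAGE_PERCENT = 0.08


def divergence_table() -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in DIVERGENCE_ROWS])
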