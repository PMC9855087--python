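"""Per-analyte dose arithmetic for a gavage-administered oil supplement.

Given the supplement's fatty-acid composition (g per 100 g of oil) and a
daily dose rate in mg of oil per g of body weight, each analyte's dose is
``rate * content / 100`` mg per g body weight, displayed to three decimals
(half away from zero). Class totals (omega-3/6/9, SFA, MUFA, PUFA) are
summed from unrounded member doses and rounded last.

The class tags in the bundled composition table follow the source batch
sheet's group membership verbatim, which is what its printed totals sum to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

DEFAULT_DOSE_RATE = 2.82  # mg oil per g body weight per day

CLASS_ORDER = ["omega3", "omega6", "omega9", "SFA", "MUFA", "PUFA"]
CLASS_LABELS = {
    "omega3": "Total ω3",
    "omega6": "Total ω6",
    "omega9": "Total ω9",
    "SFA": "SFAs",
    "MUFA": "MUFAs",
    "PUFA": "PUFAs",
}


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (banker's rounding would bias table totals)."""
    scale = 10**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


@dataclass
class CompositionRow:
    name: str
    shorthand: str
    classes: tuple[str, ...]
    content: float  # g per 100 g oil

    def __post_init__(self) -> None:
        if self.content < 0:
            raise ValueError(f"{self.name}: negative content")
        unknown = set(self.classes) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"{self.name}: unknown class tags {sorted(unknown)}")


@dataclass
class CompositionTable:
    rows: list[CompositionRow]

    def __post_init__(self) -> None:
        keys = [(r.name, r.shorthand) for r in self.rows]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (name, shorthand) pairs in composition table")

    def row(self, shorthand: str) -> CompositionRow:
        for r in self.rows:
            if r.shorthand == shorthand:
                return r
        raise KeyError(shorthand)

    @classmethod
    def from_tsv(cls, path) -> "CompositionTable":
        df = pd.read_csv(path, sep="\t", dtype={"classes": str})
        rows = []
        for rec in df.itertuples(index=False):
            tags = tuple(t for t in str(rec.classes).split(";") if t and t != "nan")
            rows.append(CompositionRow(rec.name, rec.shorthand, tags, float(rec.g_per_100g)))
        return cls(rows)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "name": [r.name for r in self.rows],
                "shorthand": [r.shorthand for r in self.rows],
                "classes": [";".join(r.classes) for r in self.rows],
                "g_per_100g": [r.content for r in self.rows],
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DoseRow:
    name: str
    shorthand: str
    dose: float        # mg per g bw, rounded to 3 decimals
    dose_exact: float  # unrounded


@dataclass
class DoseTable:
    rows: list[DoseRow]
    class_totals: dict[str, float]        # rounded
    class_totals_exact: dict[str, float]  # unrounded
    dose_rate: float

    def dose(self, shorthand: str) -> float:
        for r in self.rows:
            if r.shorthand == shorthand:
                return r.dose
        raise KeyError(shorthand)

    def to_frame(self) -> pd.DataFrame:
        names = [r.name for r in self.rows]
        shorts = [r.shorthand for r in self.rows]
        doses = [r.dose for r in self.rows]
        for tag, total in self.class_totals.items():
            names.append(CLASS_LABELS[tag])
            shorts.append("")
            doses.append(total)
        return pd.DataFrame(
            {"name": names, "shorthand": shorts, "dose_mg_per_g_bw": doses}
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df["dose_mg_per_g_bw"] = df["dose_mg_per_g_bw"].map(lambda x: f"{x:.3f}")
        df.to_csv(path, sep="\t", index=False)


def compute_doses(
    comp: CompositionTable, dose_rate: float = DEFAULT_DOSE_RATE
) -> DoseTable:
    """Per-analyte and per-class daily dose (mg per g body weight)."""
    if dose_rate <= 0:
        raise ValueError("dose_rate must be positive")
    rows = []
    totals_exact = {tag: 0.0 for tag in CLASS_ORDER}
    for r in comp.rows:
        exact = dose_rate * r.content / 100.0
        rows.append(DoseRow(r.name, r.shorthand, round_half_away(exact, 3), exact))
        for tag in r.classes:
            totals_exact[tag] += exact
    totals = {tag: round_half_away(v, 3) for tag, v in totals_exact.items()}
    return DoseTable(rows, totals, totals_exact, dose_rate)


def daily_intake_range(
    dose_rate: float, bw_range: tuple[float, float]
) -> tuple[float, float]:
    """Total daily supplement intake (mg) across a body-weight range (g)."""
    lo, hi = bw_range
    if not 0 < lo <= hi:
        raise ValueError("body-weight range must satisfy 0 < low <= high")
    if dose_rate <= 0:
        raise ValueError("dose_rate must be positive")
    return round_half_away(dose_rate * lo, 1), round_half_away(dose_rate * hi, 1)


def load_bundled_composition() -> CompositionTable:
    """Composition of the supplement batch shipped with the package."""
    ref = resources.files("circuitrank").joinpath("data/efa_composition.tsv")
    with resources.as_file(ref) as path:
        return CompositionTable.from_tsv(Path(path))
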