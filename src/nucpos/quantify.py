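"""Replicate quantification: percent of a reference condition's mean, with SD.

Band or blot intensities (densitometry output, consumed here as a tidy table)
are expressed as a percentage of the mean intensity of a designated reference
condition.  The reference mean is 100% by construction; per-condition spread
is the sample standard deviation over biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("condition", "replicate", "intensity")


@dataclass
class ReplicateTable:
    """Tidy intensities (condition, replicate, intensity) plus the reference condition."""

    data: pd.DataFrame
    reference_condition: str

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"replicate table missing columns {missing}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.reference_condition not in set(self.data["condition"]):
            raise ValueError(
                f"reference condition {self.reference_condition!r} not present in table"
            )


@dataclass
class RelativeQuantResult:
    """Per-condition percentages of the reference mean, with mean and sample SD."""

    condition: str
    values_pct: list[float]
    mean_pct: float
    sd_pct: float
    n: int


def read_replicate_table(path, reference_condition: str, sep: str | None = None) -> ReplicateTable:
    """Read a tab- or comma-separated replicate intensity table."""
    data = pd.read_csv(path, sep=sep, engine="python")
    return ReplicateTable(data=data, reference_condition=reference_condition)


def relative_to_reference(table: ReplicateTable) -> list[RelativeQuantResult]:
    """Express every intensity as a percentage of the reference condition's mean.

    Each intensity becomes ``100 * intensity / mean(reference intensities)``;
    per-condition mean and sample SD (n-1 denominator) are reported.  The
    reference condition's mean is exactly 100.  Conditions with a single
    replicate get SD 0.
    """
    ref = table.data.loc[table.data["condition"] == table.reference_condition, "intensity"]
    ref_mean = float(ref.mean())
    if ref_mean == 0:
        raise ValueError("reference condition mean intensity is zero")

    results = []
    for condition, group in table.data.groupby("condition", sort=False):
        pct = (100.0 * group["intensity"] / ref_mean).to_numpy()
        sd = float(np.std(pct, ddof=1)) if len(pct) > 1 else 0.0
        results.append(
            RelativeQuantResult(
                condition=str(condition),
                values_pct=[float(v) for v in pct],
                mean_pct=float(np.mean(pct)),
                sd_pct=sd,
                n=len(pct),
            )
        )
    return results


def results_to_frame(results: list[RelativeQuantResult]) -> pd.DataFrame:
    """Summarize quantification results as a DataFrame (one row per condition)."""
    return pd.DataFrame(
        {
            "condition": [r.condition for r in results],
            "mean_pct": [r.mean_pct for r in results],
            "sd_pct": [r.sd_pct for r in results],
            "n": [r.n for r in results],
        }
    )
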