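"""Summary statistics over accepted miRNA records.

Means and dispersions over mature length, |MFE|, precursor length and MFEI,
plus arm counts and the share of 21-nt matures.  Standard deviations use the
sample (n-1) convention; the population (n) value is also carried for
reporting since published "+/-" dispersions rarely state a convention.
Rounding happens only at the report boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._sequtils import round_half_up
from .hairpin_eval import MirnaRecord


@dataclass(frozen=True)
class MirnaSummary:
    n: int
    mature_len_mean: float
    mature_len_sd: float
    n_len_21: int
    pct_len_21: float
    n_arm5: int
    n_arm3: int
    mfe_mean_abs: float
    mfe_sd: float
    mfe_min_abs: float
    mfe_max_abs: float
    pl_min: int
    pl_max: int
    pl_mean: float
    pl_sd: float
    mfei_mean: float
    mfei_sd: float
    mfei_min: float
    mfei_max: float

    def __post_init__(self) -> None:
        if self.n_arm5 + self.n_arm3 != self.n:
            raise ValueError("arm counts must partition the records")
        for lo, mean, hi in (
            (self.mfe_min_abs, self.mfe_mean_abs, self.mfe_max_abs),
            (self.pl_min, self.pl_mean, self.pl_max),
            (self.mfei_min, self.mfei_mean, self.mfei_max),
        ):
            if not lo <= mean <= hi:
                raise ValueError("min <= mean <= max violated")


def _sd(values: np.ndarray) -> float:
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def summarize(records: Sequence[MirnaRecord]) -> MirnaSummary:
    """Aggregate a record set; errors on empty input."""
    if not records:
        raise ValueError("cannot summarize an empty record set")
    ml = np.array([r.mature_len for r in records], dtype=float)
    mfe = np.array([r.mfe_abs for r in records], dtype=float)
    pl = np.array([r.precursor_len for r in records], dtype=float)
    fei = np.array([r.mfei for r in records], dtype=float)
    arms = [r.arm for r in records]
    bad = set(arms) - {"5p", "3p"}
    if bad:
        raise ValueError(f"records with unassigned arm: {sorted(bad)}")
    n = len(records)
    n21 = int((ml == 21).sum())
    return MirnaSummary(
        n=n,
        mature_len_mean=float(ml.mean()),
        mature_len_sd=_sd(ml),
        n_len_21=n21,
        pct_len_21=round_half_up(n21 / n * 100, 1),
        n_arm5=arms.count("5p"),
        n_arm3=arms.count("3p"),
        mfe_mean_abs=float(mfe.mean()),
        mfe_sd=_sd(mfe),
        mfe_min_abs=float(mfe.min()),
        mfe_max_abs=float(mfe.max()),
        pl_min=int(pl.min()),
        pl_max=int(pl.max()),
        pl_mean=float(pl.mean()),
        pl_sd=_sd(pl),
        mfei_mean=float(fei.mean()),
        mfei_sd=_sd(fei),
        mfei_min=float(fei.min()),
        mfei_max=float(fei.max()),
    )


def summary_report(summary: MirnaSummary) -> dict[str, float | int]:
    """Report-rounded view of a summary (half-up at the printed precision)."""
    s = summary
    return {
        "n": s.n,
        "mature_len_mean": round_half_up(s.mature_len_mean, 1),
        "mature_len_sd_sample": round_half_up(s.mature_len_sd, 1),
        "n_len_21": s.n_len_21,
        "pct_len_21": s.pct_len_21,
        "n_arm5": s.n_arm5,
        "n_arm3": s.n_arm3,
        "mfe_mean_abs": round_half_up(s.mfe_mean_abs, 2),
        "mfe_sd_sample": round_half_up(s.mfe_sd, 2),
        "mfe_min_abs": round_half_up(s.mfe_min_abs, 1),
        "mfe_max_abs": round_half_up(s.mfe_max_abs, 1),
        "pl_min": s.pl_min,
        "pl_max": s.pl_max,
        "pl_mean": round_half_up(s.pl_mean, 2),
        "pl_sd_sample": round_half_up(s.pl_sd, 2),
        "mfei_mean": round_half_up(s.mfei_mean, 2),
        "mfei_sd_sample": round_half_up(s.mfei_sd, 2),
        "mfei_min": round_half_up(s.mfei_min, 2),
        "mfei_max": round_half_up(s.mfei_max, 2),
    }
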