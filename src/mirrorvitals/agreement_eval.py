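"""Agreement statistics between an estimated and a reference HR series:
MAE, Pearson correlation, and Bland-Altman bias with 95% limits of
agreement (bias +/- 1.96 * SD of the differences, sample SD with n-1).
Differences are taken as estimate minus reference."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .errors import AlignmentError, ConfigurationError

LOA_MULTIPLIER = 1.96


@dataclass
class PairedSeries:
    timestamps: np.ndarray
    estimate: np.ndarray
    reference: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.estimate = np.asarray(self.estimate, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (len(self.timestamps) == len(self.estimate) == len(self.reference)):
            raise ConfigurationError("paired series must have equal lengths")
        if len(self.estimate) < 2:
            raise ConfigurationError("paired series needs at least 2 points")
        if not (np.all(np.isfinite(self.estimate)) and np.all(np.isfinite(self.reference))):
            raise ConfigurationError("paired series contains non-finite values")


@dataclass
class AgreementReport:
    n: int
    mae: float
    pearson_r: Optional[float]
    pearson_defined: bool
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "pearson_defined": self.pearson_defined,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def align_series(
    est_t: np.ndarray,
    est_v: np.ndarray,
    ref_t: np.ndarray,
    ref_v: np.ndarray,
    max_gap_s: float = 0.5,
) -> PairedSeries:
    """Nearest-neighbour pairing of two timestamped series within ``max_gap_s``.

    Each estimate sample pairs with the closest reference timestamp; pairs
    farther apart than ``max_gap_s`` are dropped and counted.
    """
    est_t = np.asarray(est_t, dtype=float)
    est_v = np.asarray(est_v, dtype=float)
    ref_t = np.asarray(ref_t, dtype=float)
    ref_v = np.asarray(ref_v, dtype=float)
    if len(est_t) == 0 or len(ref_t) == 0:
        raise AlignmentError("cannot align empty series")
    order = np.argsort(ref_t)
    ref_t, ref_v = ref_t[order], ref_v[order]
    idx = np.searchsorted(ref_t, est_t)
    ts, ev, rv = [], [], []
    dropped = 0
    for i, t in enumerate(est_t):
        candidates = [j for j in (idx[i] - 1, idx[i]) if 0 <= j < len(ref_t)]
        j = min(candidates, key=lambda j: abs(ref_t[j] - t))
        if abs(ref_t[j] - t) <= max_gap_s:
            ts.append(t)
            ev.append(est_v[i])
            rv.append(ref_v[j])
        else:
            dropped += 1
    if len(ts) == 0:
        raise AlignmentError(f"no pairs within {max_gap_s}s (dropped {dropped})")
    return PairedSeries(np.array(ts), np.array(ev), np.array(rv), n_dropped=dropped)


def agreement(pairs: PairedSeries) -> AgreementReport:
    """MAE, Pearson r, and Bland-Altman bias / 95% limits of agreement."""
    e, r = pairs.estimate, pairs.reference
    d = e - r
    n = len(d)
    mae = float(np.mean(np.abs(d)))
    bias = float(np.mean(d))
    sd_diff = float(np.std(d, ddof=1))
    if np.all(e == e[0]) or np.all(r == r[0]):
        pearson, defined = None, False
    else:
        pearson, defined = float(stats.pearsonr(e, r).statistic), True
    return AgreementReport(
        n=n,
        mae=mae,
        pearson_r=pearson,
        pearson_defined=defined,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - LOA_MULTIPLIER * sd_diff,
        loa_high=bias + LOA_MULTIPLIER * sd_diff,
    )
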