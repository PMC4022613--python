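"""Signal-intensity distribution characteristics, SIC and MSI.

The signal-intensity coefficient (SIC) is ``1 - p/256`` where ``p`` is the
25th-percentile intensity of the pericardial pixel sample.  Percentiles use
the nearest-rank order statistic (no interpolation), so ``p`` is always an
observed 8-bit value and the SIC lies on the lattice ``{1 - k/256}``.

The myocardial structural index (MSI) combines the SIC with relative wall
thickness: ``MSI = SIC/0.13 + RWT/0.05``.  The two scaling constants are
fixed literals of the method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from echostruct.imaging_io import PixelSample

PERCENTILE_RANKS = (5, 10, 25, 50, 75, 90, 95)

#: minimum pericardial sample size for a stable 25th percentile
MIN_SAMPLE_SIZE = 32

SIC_SCALE = 0.13
RWT_SCALE = 0.05


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    mean: float
    sd: float
    percentiles: dict
    skewness: float
    excess_kurtosis: float


@dataclass(frozen=True)
class MicrostructureResult:
    sic: float
    p25: int
    summary: DistributionSummary
    roi_label: str = "pericardial"
    source_id: str = ""
    frame_index: int = 0

    def to_record(self) -> dict:
        """Flat JSON-serializable record for batch output."""
        rec = {
            "source_id": self.source_id,
            "frame_index": self.frame_index,
            "roi_label": self.roi_label,
            "n": self.summary.n,
            "p25": self.p25,
            "sic": self.sic,
            "mean": self.summary.mean,
            "sd": self.summary.sd,
        }
        for q, v in self.summary.percentiles.items():
            rec[f"pct{q}"] = v
        return rec


@dataclass(frozen=True)
class MsiResult:
    msi: float
    sic_component: float
    rwt_component: float


def _as_values(sample) -> np.ndarray:
    if isinstance(sample, PixelSample):
        return sample.intensities
    return np.asarray(sample).ravel()


def percentile_nearest_rank(sample, q: float) -> int:
    """The ceil(q*n/100)-th smallest value; always an observed value."""
    values = _as_values(sample)
    n = values.size
    if n < 1:
        raise ValueError("empty sample")
    if not 0 < q <= 100:
        raise ValueError(f"percentile rank must be in (0, 100], got {q}")
    # 1-based; epsilon guards ceil against float error at exact integers
    rank = math.ceil(q * n / 100.0 - 1e-9)
    rank = min(max(rank, 1), n)
    return int(np.partition(values, rank - 1)[rank - 1])


def distribution_summary(sample) -> DistributionSummary:
    """Moments (sd with n-1 denominator) and nearest-rank percentiles."""
    values = _as_values(sample).astype(np.float64)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values for a distribution summary")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    dev = values - mean
    if sd > 0:
        m2 = float(np.mean(dev**2))
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    pcts = {q: percentile_nearest_rank(values.astype(np.int64), q) for q in PERCENTILE_RANKS}
    return DistributionSummary(
        n=int(n), mean=mean, sd=sd, percentiles=pcts, skewness=skew, excess_kurtosis=kurt
    )


def compute_sic(
    sample: PixelSample,
    min_sample_size: int = MIN_SAMPLE_SIZE,
    strict_label: bool = False,
) -> MicrostructureResult:
    """SIC = 1 - p/256 with p the 25th-percentile pericardial intensity."""
    values = _as_values(sample)
    if values.size < min_sample_size:
        raise ValueError(
            f"sample of {values.size} pixels is below the minimum of {min_sample_size}"
        )
    roi_label = sample.roi_label if isinstance(sample, PixelSample) else "pericardial"
    if roi_label != "pericardial":
        msg = f"SIC is defined on the pericardial ROI; got label {roi_label!r}"
        if strict_label:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    p25 = percentile_nearest_rank(values, 25)
    sic = 1.0 - p25 / 256.0
    return MicrostructureResult(
        sic=sic,
        p25=p25,
        summary=distribution_summary(values),
        roi_label=roi_label,
        source_id=getattr(sample, "source_id", ""),
        frame_index=getattr(sample, "frame_index", 0),
    )


def compute_msi(sic: float, rwt: float) -> MsiResult:
    """MSI = SIC/0.13 + RWT/0.05."""
    if not 0 <= sic <= 1:
        raise ValueError(f"sic must lie in [0, 1], got {sic}")
    if rwt <= 0:
        raise ValueError(f"rwt must be positive, got {rwt}")
    sic_component = sic / SIC_SCALE
    rwt_component = rwt / RWT_SCALE
    return MsiResult(
        msi=sic_component + rwt_component,
        sic_component=sic_component,
        rwt_component=rwt_component,
    )
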