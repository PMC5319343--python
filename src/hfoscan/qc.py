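"""File-level quality control for massive int16 EEG databases.

A multi-week, multi-channel recording campaign produces thousands of
flat binary files, some of which are unusable: stretches of zeros from
electrode dropouts, repeated oscillation patterns from recorder faults,
or short files from interrupted sessions. A single cheap statistic
separates them: build the per-value sample-count histogram n_j over the
full 16-bit range, difference neighbouring counts s_k = n_{k-N} -
n_{k-N-1}, and take

    sigma_s = sqrt( 1/(2N-1) * sum_k (s_k - s_bar)^2 ),   N = 2^15.

Normal files with smooth, approximately Gaussian histograms give small
sigma_s; zero-filled files put a huge spike at n_0 (sigma_s = L *
sqrt(2/(2N-1)) for an all-zero file); repeated-pattern files concentrate
counts on few values and land in between. sigma_s also grows with file
length L for a fixed distribution shape, so undersized files fall below
the normal band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RawRecording

N_ADC = 2**15  # histogram index range j = -N..N

__all__ = [
    "ValueHistogram",
    "FileQCResult",
    "QCThresholds",
    "value_histogram",
    "sigma_s",
    "classify_file",
    "qc_file",
    "qc_contour",
]


@dataclass
class ValueHistogram:
    """Integer counts n_j for j = -N..N (index j+N into ``counts``)."""

    counts: np.ndarray
    N: int = N_ADC

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size != 2 * self.N + 1:
            raise ValueError("histogram must cover j = -N..N")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def L(self) -> int:
        return int(self.counts.sum())

    @property
    def zero_fraction(self) -> float:
        return float(self.counts[self.N]) / self.L if self.L else 0.0


@dataclass
class QCThresholds:
    """Classification bands (configurable; the defaults correspond to
    ~3e8-sample files and must be rescaled for shorter files since
    sigma_s grows with L)."""

    normal_band: tuple[float, float] = (1e2, 1e3)
    corrupted_band: tuple[float, float] = (1e4, 1e5)
    zeros_min_sigma: float = 1e5
    zero_fraction_max: float = 0.01
    nominal_L: int = 300_000_000
    small_fraction: float = 0.5


@dataclass
class FileQCResult:
    sigma_s: float
    L: int
    zero_fraction: float
    file_class: str = "normal"
    warning: bool = False
    rat_id: int = 1
    channel_id: int = 1
    file_no: int = 1

    def to_row(self) -> dict:
        return {
            "rat": self.rat_id,
            "channel": self.channel_id,
            "file": self.file_no,
            "L": self.L,
            "sigma_s": self.sigma_s,
            "zero_fraction": self.zero_fraction,
            "class": self.file_class,
            "warning": self.warning,
        }


def value_histogram(rec: RawRecording) -> ValueHistogram:
    """Exact per-value tally n_j of a recording; sum n_j = L."""
    if rec.L == 0:
        raise ValueError("empty recording has no histogram")
    counts = np.bincount(
        rec.samples.astype(np.int64) + N_ADC, minlength=2 * N_ADC + 1
    )
    return ValueHistogram(counts=counts)


def sigma_s(hist: ValueHistogram) -> float:
    """Standard deviation of successive histogram differences.

    s_k = n_{k-N} - n_{k-N-1} for k = 1..2N; the variance uses the
    1/(2N-1) sample normalization around the mean s_bar (which
    telescopes to (n_N - n_{-N}) / 2N).
    """
    s = np.diff(hist.counts.astype(np.float64))
    return float(np.sqrt(np.var(s, ddof=1)))


def classify_file(
    sig: float,
    L: int,
    zero_fraction: float,
    thresholds: QCThresholds | None = None,
) -> tuple[str, bool]:
    """Deterministic class from the configured bands.

    Returns (class, warning). sigma_s values falling between bands
    default to ``normal`` with the warning flag set (near-seizure files
    legitimately spill above the good band).
    """
    th = thresholds or QCThresholds()
    warning = False
    if sig > th.zeros_min_sigma or zero_fraction > th.zero_fraction_max:
        base = "zeros"
    elif th.corrupted_band[0] <= sig <= th.corrupted_band[1]:
        base = "corrupted"
    else:
        base = "normal"
        if not (th.normal_band[0] <= sig <= th.normal_band[1]):
            warning = True
    small = L < th.small_fraction * th.nominal_L
    if small:
        cls = {"normal": "small", "zeros": "small_zeros", "corrupted": "small_corrupted"}[
            base
        ]
    else:
        cls = base
    return cls, warning


def qc_file(rec: RawRecording, thresholds: QCThresholds | None = None) -> FileQCResult:
    """Full QC of one recording: histogram, sigma_s, classification."""
    hist = value_histogram(rec)
    sig = sigma_s(hist)
    zf = hist.zero_fraction
    cls, warning = classify_file(sig, rec.L, zf, thresholds)
    return FileQCResult(
        sigma_s=sig,
        L=rec.L,
        zero_fraction=zf,
        file_class=cls,
        warning=warning,
        rat_id=rec.rat_id,
        channel_id=rec.channel_id,
        file_no=rec.file_no,
    )


@dataclass
class QCContour:
    """log10(sigma_s) on a channel x file grid; NaN where files are absent."""

    grid: pd.DataFrame
    good_band: tuple[float, float] = (1e2, 1e3)
    masked: bool = False
    sentinel: float = 50.0


def qc_contour(
    results: list[FileQCResult],
    good_band: tuple[float, float] = (1e2, 1e3),
    mask_outside: bool = False,
    sentinel: float = 50.0,
) -> QCContour:
    """Assemble per-file sigma_s values into a channel x file contour.

    With ``mask_outside`` the cells whose sigma_s falls outside the good
    band are set to the sentinel value (default 50) so abnormal data
    stand out as one flat region.
    """
    if not results:
        raise ValueError("no QC results")
    keys = [(r.channel_id, r.file_no) for r in results]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (channel, file) keys")
    rows = []
    for r in results:
        if mask_outside and not (good_band[0] <= r.sigma_s <= good_band[1]):
            val = sentinel
        else:
            val = np.log10(r.sigma_s) if r.sigma_s > 0 else -np.inf
        rows.append({"channel": r.channel_id, "file": r.file_no, "value": val})
    grid = pd.DataFrame(rows).pivot(index="channel", columns="file", values="value")
    return QCContour(grid=grid, good_band=good_band, masked=mask_outside, sentinel=sentinel)


def qc_report(results: list[FileQCResult]) -> pd.DataFrame:
    """Tabular QC report (one row per file)."""
    return pd.DataFrame([r.to_row() for r in results])
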