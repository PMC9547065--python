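"""Contact-matrix topology: expected-by-distance, A/B compartments, insulation.

The compartment caller is the canonical first-principal-component method:
observed/expected normalization, Pearson correlation across bins, leading
eigenvector, sign oriented by an external activity track (positive = A).
Insulation follows the diamond convention: for each bin, the mean contact
over the off-diagonal ``w x w`` square immediately upstream x downstream,
log2-normalized by the chromosome-wide mean. Minima of the track mark
domain boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import GenomeBuild, GenomicInterval, SignalTrack

__all__ = [
    "ContactMatrix",
    "InsulationTrack",
    "CompartmentCall",
    "expected_by_distance",
    "observed_over_expected",
    "compartment_call",
    "diamond_insulation",
    "tad_boundary_insulation",
]


class ContactMatrix:
    """Symmetric binned cis contact matrix for one chromosome.

    Parameters
    ----------
    chrom, bin_size : coordinates of the binning.
    matrix : square symmetric nonnegative array of contact counts.
    mask : optional boolean validity per bin; masked (False) bins are
        excluded from every statistic. Defaults to all-valid.
    """

    def __init__(self, chrom: str, bin_size: int, matrix: np.ndarray, mask: np.ndarray | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(matrix, matrix.T, rtol=1e-8, atol=1e-8):
            raise ValueError("contact matrix must be symmetric")
        if (matrix < 0).any():
            raise ValueError("contact matrix must be nonnegative")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.matrix = matrix
        self.mask = np.ones(matrix.shape[0], dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if self.mask.shape != (matrix.shape[0],):
            raise ValueError("mask length must equal bin count")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        return pos // self.bin_size


@dataclass
class InsulationTrack:
    """Per-bin log2 insulation with validity flags."""

    chrom: str
    bin_size: int
    window_bp: int
    values: np.ndarray  # log2 scale; NaN where invalid
    valid: np.ndarray

    def value_at(self, pos: int) -> float:
        return float(self.values[pos // self.bin_size])

    def valid_at(self, pos: int) -> bool:
        b = pos // self.bin_size
        return 0 <= b < len(self.valid) and bool(self.valid[b])


@dataclass
class CompartmentCall:
    """A/B compartment segmentation with per-bin eigenvector values."""

    chrom: str
    bin_size: int
    eigenvector: np.ndarray  # NaN at invalid bins
    labels: list[str]        # per-bin "A" / "B" / "" (invalid)
    segments: list[tuple[GenomicInterval, str, float]] = field(default_factory=list)

    def label_at(self, chrom: str, pos: int) -> str:
        """Compartment label of the segment containing a position; ''
        when no segment covers it."""
        if chrom != self.chrom:
            return ""
        for seg, lab, _ in self.segments:
            if seg.start <= pos < seg.end:
                return lab
        return ""


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean contact per genomic separation d (in bins) over valid pixels.

    Entry d is the mean of matrix[i, i+d] over pairs with both bins valid;
    NaN where a diagonal has no valid pixel.
    """
    n = cm.n_bins
    out = np.full(n, np.nan)
    valid = cm.mask
    for d in range(n):
        vi = valid[: n - d] & valid[d:]
        if vi.any():
            out[d] = np.diagonal(cm.matrix, offset=d)[vi].mean()
    return out


def observed_over_expected(cm: ContactMatrix) -> np.ndarray:
    """O/E matrix: each pixel divided by the mean of its diagonal (NaN-safe)."""
    exp = expected_by_distance(cm)
    n = cm.n_bins
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = cm.matrix / exp[d]
    oe[~np.isfinite(oe)] = np.nan
    return oe


def compartment_call(
    cm: ContactMatrix,
    reference_track: SignalTrack | np.ndarray,
    min_valid_bins: int = 10,
) -> CompartmentCall:
    """Call A/B compartments as the leading eigenvector of the O/E correlation.

    The eigenvector sign is arbitrary; it is oriented so that bins whose
    reference signal (gene density or active-mark coverage) is above the
    median average positive, then positive bins are labelled A and negative
    B. Consecutive same-label bins merge into segments; invalid bins break
    segments.
    """
    n = cm.n_bins
    if isinstance(reference_track, SignalTrack):
        ref = _bin_reference(reference_track, cm)
    else:
        ref = np.asarray(reference_track, dtype=float)
        if ref.shape != (n,):
            raise ValueError("reference array length must equal bin count")

    oe = observed_over_expected(cm)
    valid = cm.mask.copy()
    # bins with no finite O/E information or zero variance cannot correlate
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_sd = np.nanstd(np.where(np.isfinite(oe), oe, np.nan), axis=1)
    valid &= np.isfinite(row_sd) & (row_sd > 0)
    if valid.sum() < min_valid_bins:
        raise ValueError("no compartment signal: fewer than "
                         f"{min_valid_bins} informative bins")

    sub = oe[np.ix_(valid, valid)]
    sub = np.where(np.isfinite(sub), sub, np.nanmean(sub))
    corr = np.corrcoef(sub)
    if not np.isfinite(corr).all():
        raise ValueError("no compartment signal: degenerate correlation matrix")
    w, v = np.linalg.eigh(corr)
    ev = v[:, -1]
    if w[-1] <= 1e-12:
        raise ValueError("no compartment signal: rank-0 correlation matrix")

    full_ev = np.full(n, np.nan)
    full_ev[valid] = ev
    # sign is arbitrary in PCA: orient so the eigenvector covaries
    # positively with the activity reference (positive = A)
    ref_valid = ref[valid]
    cov = float(np.cov(ev, ref_valid)[0, 1]) if np.std(ref_valid) > 0 else 0.0
    if cov < 0:
        full_ev = -full_ev
    elif cov == 0:
        hi = ref_valid > np.median(ref_valid)
        if hi.any() and ev[hi].mean() < 0:
            full_ev = -full_ev

    labels = ["" for _ in range(n)]
    for i in range(n):
        if np.isfinite(full_ev[i]):
            labels[i] = "A" if full_ev[i] > 0 else "B"

    segments: list[tuple[GenomicInterval, str, float]] = []
    i = 0
    while i < n:
        if not labels[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        seg_ev = float(np.nanmean(full_ev[i : j + 1]))
        segments.append((
            GenomicInterval(cm.chrom, i * cm.bin_size, (j + 1) * cm.bin_size),
            labels[i],
            seg_ev,
        ))
        i = j + 1
    return CompartmentCall(cm.chrom, cm.bin_size, full_ev, labels, segments)


def _bin_reference(track: SignalTrack, cm: ContactMatrix) -> np.ndarray:
    """Aggregate a finer signal track onto the matrix bin grid."""
    arr = track.values[cm.chrom]
    ratio = cm.bin_size / track.bin_size
    out = np.zeros(cm.n_bins)
    for b in range(cm.n_bins):
        lo = int(b * ratio)
        hi = min(int(np.ceil((b + 1) * ratio)), len(arr))
        if hi > lo:
            out[b] = arr[lo:hi].mean()
    return out


def diamond_insulation(cm: ContactMatrix, window_bp: int = 100_000) -> InsulationTrack:
    """Diamond insulation score per bin.

    For bin i with window w = window_bp / bin_size, the raw score is the
    mean of valid pixels in rows i-w..i-1 x columns i+1..i+w; the reported
    value is log2(raw / chromosome-wide mean of raw). The first and last w
    bins are undefined, as are bins whose diamond holds no valid pixel.
    """
    if window_bp % cm.bin_size != 0:
        raise ValueError("window_bp must be a multiple of bin_size")
    w = window_bp // cm.bin_size
    n = cm.n_bins
    if w < 1 or w >= n:
        raise ValueError(f"window of {w} bins infeasible for {n}-bin chromosome")

    # summed-area tables over valid pixels
    pix_valid = np.outer(cm.mask, cm.mask).astype(float)
    vals = cm.matrix * pix_valid
    S = vals.cumsum(axis=0).cumsum(axis=1)
    C = pix_valid.cumsum(axis=0).cumsum(axis=1)

    def box(r0, r1, c0, c1, T):
        """Sum of T over rows r0..r1, cols c0..c1 inclusive."""
        tot = T[r1, c1]
        if r0 > 0:
            tot -= T[r0 - 1, c1]
        if c0 > 0:
            tot -= T[r1, c0 - 1]
        if r0 > 0 and c0 > 0:
            tot += T[r0 - 1, c0 - 1]
        return tot

    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        cnt = box(i - w, i - 1, i + 1, i + w, C)
        if cnt > 0:
            raw[i] = box(i - w, i - 1, i + 1, i + w, S) / cnt
    valid = np.isfinite(raw) & (raw > 0)
    mean_raw = raw[valid].mean() if valid.any() else np.nan
    values = np.full(n, np.nan)
    values[valid] = np.log2(raw[valid] / mean_raw)
    return InsulationTrack(cm.chrom, cm.bin_size, window_bp, values, valid)


def tad_boundary_insulation(
    tads: list[GenomicInterval],
    tracks: dict[str, InsulationTrack] | InsulationTrack,
) -> list[dict]:
    """Mean insulation at each TAD's two boundary bins.

    A boundary contributes the insulation value of the bin containing it;
    an invalid boundary bin is skipped and the TAD flagged. Lower values
    mean stronger insulation.
    """
    if isinstance(tracks, InsulationTrack):
        tracks = {tracks.chrom: tracks}
    out = []
    for tad in tads:
        track = tracks.get(tad.chrom)
        rec = {"tad": tad, "score": np.nan, "n_valid_boundaries": 0, "flagged": True}
        if track is not None:
            n = len(track.values)
            vals = []
            for pos in (tad.start, tad.end):
                b = min(pos // track.bin_size, n - 1)
                if track.valid[b]:
                    vals.append(track.values[b])
            if vals:
                rec["score"] = float(np.mean(vals))
                rec["n_valid_boundaries"] = len(vals)
                rec["flagged"] = len(vals) < 2
        out.append(rec)
    return out
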