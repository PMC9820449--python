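"""Length-normalized nearest-neighbor Hamming distances and automatic
clonal-distance threshold detection.

The distance-to-nearest distribution of junction sequences in a repertoire is
typically bimodal: a low mode of within-clone relationships and a high mode of
unrelated rearrangements.  The threshold detector smooths the histogram and
takes the first non-declining bin after the first peak — deliberately not the
inter-mode local minimum, which is undetectable on repertoires whose between-
clone mode is shallow or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .airr_io import Repertoire


class ThresholdNotFoundError(RuntimeError):
    """No clonal threshold detectable from the distance histogram."""


@dataclass
class DistanceProfile:
    """Per-record nearest-neighbor distances plus histogram/threshold state.

    Histogram bins are centered on the grid 0, bin_width, 2*bin_width, ...
    so a detected threshold always lies on that grid.
    """

    distances: np.ndarray
    bin_width: float = 0.01
    histogram: np.ndarray = field(default=None)  # type: ignore[assignment]
    smoothed: np.ndarray | None = None
    peak_index: int | None = None
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.histogram is None:
            centers = self.bin_centers()
            edges = np.concatenate([centers - self.bin_width / 2, [centers[-1] + self.bin_width / 2]])
            self.histogram, _ = np.histogram(self.distances, bins=edges)

    def bin_centers(self) -> np.ndarray:
        n_bins = int(round(1.0 / self.bin_width)) + 1
        return np.arange(n_bins) * self.bin_width


def normalized_hamming(a: str, b: str) -> float:
    """Hamming distance normalized by length, ambiguity-tolerant.

    A position where either string carries a symbol outside {A,C,G,T}
    contributes no mismatch.  Raises on unequal or zero length.
    """
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("sequences must be non-empty")
    return hamming_mismatches(a, b) / len(a)


_ACGT = frozenset("ACGT")


def hamming_mismatches(a: str, b: str) -> int:
    """Mismatch count with non-ACGT symbols acting as wildcards."""
    return sum(1 for x, y in zip(a, b) if x != y and x in _ACGT and y in _ACGT)


def _compatible(r1, r2) -> bool:
    return (
        len(r1.junction) == len(r2.junction)
        and bool(r1.v_genes & r2.v_genes)
        and bool(r1.j_genes & r2.j_genes)
    )


def dist_to_nearest(rep: Repertoire, bin_width: float = 0.01) -> DistanceProfile:
    """Distance-to-nearest profile over junction sequences.

    For each record the distance is the minimum normalized junction Hamming
    distance to any other record sharing its junction length and overlapping
    its V and J gene sets (gene level; records with ambiguous calls take the
    minimum over every partition their calls allow).  Records with no such
    partner are excluded.
    """
    recs = list(rep.records)
    by_len: dict[int, list[int]] = {}
    for i, r in enumerate(recs):
        by_len.setdefault(len(r.junction), []).append(i)
    nearest = np.full(len(recs), np.inf)
    for idxs in by_len.values():
        for ai in range(len(idxs)):
            i = idxs[ai]
            for bi in range(ai + 1, len(idxs)):
                j = idxs[bi]
                if not _compatible(recs[i], recs[j]):
                    continue
                d = normalized_hamming(recs[i].junction, recs[j].junction)
                if d < nearest[i]:
                    nearest[i] = d
                if d < nearest[j]:
                    nearest[j] = d
    return DistanceProfile(distances=nearest[np.isfinite(nearest)], bin_width=bin_width)


def smooth_histogram(histogram: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average; the window truncates at the edges."""
    h = np.asarray(histogram, dtype=float)
    k = window // 2
    return np.array([h[max(0, i - k) : i + k + 1].mean() for i in range(len(h))])


def find_threshold(
    profile: DistanceProfile,
    smooth_window: int = 5,
    noise_frac: float = 0.01,
    variant: str = "stop",
) -> float:
    """Detect the clonal distance threshold from the smoothed histogram.

    The smoothed series s is scanned for the first peak (s[i-1] < s[i] >=
    s[i+1], with s[i] at least ``noise_frac`` of the total count to skip
    spurious single-count bins).  The threshold is the center of the first
    bin after the peak at which the series has stopped declining.  Two
    readings of "non-declining" exist and differ by one bin at a strict
    minimum:

    - ``variant="stop"`` (default): first j > peak with s[j+1] >= s[j] —
      decline ends at j, so the rule fires exactly at a strict inter-mode
      valley and never beyond it;
    - ``variant="next"``: first j > peak with s[j] >= s[j-1] — the first
      bin that itself fails to decline, one bin later at strict minima.

    Raises :class:`ThresholdNotFoundError` when no peak qualifies or the
    series declines all the way to the last bin.
    """
    if variant not in ("stop", "next"):
        raise ValueError(f"unknown variant {variant!r} (use 'stop' or 'next')")
    h = np.asarray(profile.histogram, dtype=float)
    if h.size == 0 or h.sum() == 0:
        raise ThresholdNotFoundError("empty distance histogram")
    s = smooth_histogram(h, smooth_window)
    profile.smoothed = s
    floor = noise_frac * h.sum()
    peak = None
    for i in range(len(s)):
        left = s[i - 1] if i > 0 else -np.inf
        right = s[i + 1] if i < len(s) - 1 else -np.inf
        if left < s[i] and s[i] >= right and s[i] >= floor:
            peak = i
            break
    if peak is None:
        raise ThresholdNotFoundError(
            "no peak found in smoothed distance histogram; "
            "supply the threshold manually (--threshold)"
        )
    profile.peak_index = peak
    centers = profile.bin_centers()
    for j in range(peak + 1, len(s)):
        if variant == "stop":
            non_declining = j + 1 < len(s) and s[j + 1] >= s[j]
        else:
            non_declining = s[j] >= s[j - 1]
        if non_declining:
            profile.threshold = float(centers[j])
            return profile.threshold
    raise ThresholdNotFoundError(
        "smoothed histogram declines monotonically after the first peak; "
        "supply the threshold manually (--threshold)"
    )
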