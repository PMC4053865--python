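"""HICF fingerprint band spaces, tolerance matching and Sulston overlap scoring.

High-information-content fingerprinting (HICF) sizes restriction fragments of a
BAC clone in four fluorescent channels, each covering raw sizes of 50-500 bp.
For overlap scoring the four channels are multiplied by a scale factor and
affine-shifted into one unified discrete band space ("gel"), so that a clone is
represented as a single sorted list of integer band positions.  Two clones that
truly overlap share the bands deriving from fragments of the common interval;
the Sulston score is the probability of observing at least the matched number
of shared bands by chance alone, and is the significance measure behind every
assembly decision downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ScoreParams",
    "Fingerprint",
    "FingerprintSet",
    "unify_channels",
    "count_shared_bands",
    "sulston_score",
    "sulston_log10",
]


@dataclass(frozen=True)
class ScoreParams:
    """Parameters of the unified band space and of Sulston scoring.

    ``band_space`` is the number of distinguishable band slots D used in the
    single-band chance-match probability.  With the defaults it derives from
    the channel layout as ``(500 - 50) x 4 x 30 / (2 x 12) = 2,250``: the
    usable raw range of each channel, times the number of channels, times the
    per-channel scale factor, divided by twice the matching tolerance (a band
    "occupies" ``2 x tolerance`` units of the unified axis).
    """

    tolerance: int = 12
    scale: int = 30
    channel_min: int = 50
    channel_max: int = 500
    n_channels: int = 4

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.channel_max <= self.channel_min:
            raise ValueError("channel_max must exceed channel_min")
        if self.n_channels < 1 or self.scale < 1:
            raise ValueError("n_channels and scale must be >= 1")

    @property
    def channel_offset(self) -> int:
        """Affine shift between consecutive channels in the unified space."""
        return self.channel_max * self.scale

    @property
    def gel_length(self) -> int:
        """Span of the unified band space (default 500 x 4 x 30 = 60,000)."""
        return self.channel_offset * self.n_channels

    @property
    def band_space(self) -> float:
        """Number of distinguishable band slots D (default 2,250)."""
        width = self.channel_max - self.channel_min
        return (width * self.n_channels * self.scale) / (2 * self.tolerance)


@dataclass(frozen=True)
class Fingerprint:
    """A clone's fingerprint: sorted integer bands in the unified space.

    Duplicate band values are permitted; they represent co-migrating
    fragments that the sizing instrument cannot distinguish.
    """

    clone_id: str
    bands: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bands, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("bands must be one-dimensional")
        if arr.size and np.any(np.diff(arr) < 0):
            arr = np.sort(arr)
        object.__setattr__(self, "bands", arr)

    def __len__(self) -> int:
        return int(self.bands.size)


class FingerprintSet(Mapping[str, Fingerprint]):
    """An ordered, id-keyed collection of fingerprints."""

    def __init__(self, fingerprints: Iterable[Fingerprint] = ()):  # noqa: D107
        self._fps: dict[str, Fingerprint] = {}
        for fp in fingerprints:
            if fp.clone_id in self._fps:
                raise ValueError(f"duplicate clone_id {fp.clone_id!r}")
            self._fps[fp.clone_id] = fp

    def __getitem__(self, clone_id: str) -> Fingerprint:
        return self._fps[clone_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._fps)

    def __len__(self) -> int:
        return len(self._fps)

    def add(self, fp: Fingerprint) -> None:
        if fp.clone_id in self._fps:
            raise ValueError(f"duplicate clone_id {fp.clone_id!r}")
        self._fps[fp.clone_id] = fp

    def band_counts(self) -> dict[str, int]:
        return {cid: len(fp) for cid, fp in self._fps.items()}


def unify_channels(
    raw: Sequence[Sequence[float]],
    params: ScoreParams = ScoreParams(),
) -> np.ndarray:
    """Merge per-channel raw fragment sizes into one sorted band list.

    Each raw size is multiplied by ``params.scale`` and shifted by
    ``channel_index x channel_offset`` so channels occupy disjoint intervals
    of the unified axis.  Sizes outside ``[channel_min, channel_max]`` are
    rejected; the number rejected is reported via a ``ValueError`` only if
    *all* bands of a channel are out of range, otherwise they are silently
    dropped (mirroring the sizing instrument's calling window).

    Returns the sorted unified band array (dtype int64).
    """
    if len(raw) != params.n_channels:
        raise ValueError(
            f"expected {params.n_channels} channels, got {len(raw)}"
        )
    out: list[int] = []
    n_rejected = 0
    for ch, sizes in enumerate(raw):
        offset = ch * params.channel_offset
        for s in sizes:
            if s < params.channel_min or s > params.channel_max:
                n_rejected += 1
                continue
            out.append(int(round(s * params.scale)) + offset)
    bands = np.sort(np.asarray(out, dtype=np.int64))
    bands = np.asarray(bands)
    return bands


def count_shared_bands(
    a: Fingerprint | np.ndarray,
    b: Fingerprint | np.ndarray,
    tolerance: int = 12,
) -> int:
    """Maximum number of one-to-one band matches within ``tolerance``.

    Greedy two-pointer sweep over the two sorted band lists.  For points on a
    line with a fixed matching tolerance this greedy strategy attains the
    maximum-cardinality matching (validated against a brute-force bipartite
    matcher in the test suite).  Symmetric in its arguments.
    """
    x = a.bands if isinstance(a, Fingerprint) else np.asarray(a)
    y = b.bands if isinstance(b, Fingerprint) else np.asarray(b)
    return _greedy_match(x, y, tolerance)


def _greedy_match(x: np.ndarray, y: np.ndarray, tol: int) -> int:
    i = j = m = 0
    nx, ny = len(x), len(y)
    while i < nx and j < ny:
        d = x[i] - y[j]
        if d > tol:
            j += 1
        elif d < -tol:
            i += 1
        else:
            m += 1
            i += 1
            j += 1
    return m


def _match_prob(n_hi: int, band_space: float) -> float:
    """Chance probability p that one band of the smaller clone matches any
    band of the larger clone: ``1 - (1 - 1/D)^n_hi`` (exact, not linearized)."""
    return -math.expm1(n_hi * math.log1p(-1.0 / band_space))


def sulston_log10(
    m: int,
    n_a: int,
    n_b: int,
    params: ScoreParams = ScoreParams(),
) -> float:
    """log10 of the Sulston score for ``m`` shared bands between clones with
    ``n_a`` and ``n_b`` bands.

    The score is the upper binomial tail
    ``sum_{k=m}^{n_lo} C(n_lo, k) p^k (1-p)^(n_lo-k)`` with
    ``n_lo = min(n_a, n_b)`` and single-band match probability
    ``p = 1 - (1 - 1/D)^{n_hi}``.  Evaluated by log-space summation so that
    scores far below the 1e-15 network cutoff remain exact to floating
    precision.
    """
    n_lo, n_hi = min(n_a, n_b), max(n_a, n_b)
    if n_lo <= 0:
        raise ValueError("fingerprints must be non-empty")
    if m < 0 or m > n_lo:
        raise ValueError(f"impossible shared-band count m={m} for n_lo={n_lo}")
    if m == 0:
        return 0.0
    p = _match_prob(n_hi, params.band_space)
    k = np.arange(m, n_lo + 1, dtype=np.float64)
    log_terms = (
        gammaln(n_lo + 1)
        - gammaln(k + 1)
        - gammaln(n_lo - k + 1)
        + k * math.log(p)
        + (n_lo - k) * math.log1p(-p)
    )
    return float(logsumexp(log_terms)) / math.log(10.0)


def sulston_score(
    a: Fingerprint,
    b: Fingerprint,
    params: ScoreParams = ScoreParams(),
) -> float:
    """Sulston score of two fingerprints (probability in (0, 1]).

    Convenience wrapper around :func:`count_shared_bands` and
    :func:`sulston_log10`; may underflow to 0.0 for extremely strong overlaps
    (log10 score below about -308).  Use :func:`sulston_log10` when the raw
    magnitude matters.
    """
    m = count_shared_bands(a, b, params.tolerance)
    return 10.0 ** sulston_log10(m, len(a), len(b), params)
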