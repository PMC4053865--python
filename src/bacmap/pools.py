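"""Three-dimensional MTP pool design, deconvolution and chance-call statistics.

Minimal-tiling-path clones live in 384-well plates; the screening design
pools them along three axes — plate pools, row pools (A..P) and column pools
(1..24), 57 pools in total at the default 17-plate layout.  A probe (gene /
UniGene) hybridized against all pools lights up the plate, row and column
pool of every MTP clone that carries it; inverting these signals back to
clone addresses is the deconvolution step.  Because a single clone
contributes exactly three positive pools, two or more positive pools already
pin down candidate addresses, and the chance that a probe with no true clone
reaches two positive pools is a closed-form function of the per-pool
false-positive rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PoolDesign",
    "PoolCall",
    "build_pool_design",
    "deconvolve_pools",
    "chance_positive_prob",
    "estimate_threshold",
]

AXES = ("plate", "row", "column")
ROW_LETTERS = "ABCDEFGHIJKLMNOP"


@dataclass
class PoolDesign:
    """Pools along the three axes and the clone addresses behind them."""

    pool_ids: list[str]
    pool_axis: dict[str, str]
    members: dict[str, list[str]]  # pool_id -> clone_ids
    addresses: dict[str, tuple[int, int, int]]  # clone -> (plate, row, column)

    def clone_pools(self) -> dict[str, tuple[str, str, str]]:
        """The three pools (plate, row, column) holding each clone."""
        out = {}
        for cid, (p, r, c) in self.addresses.items():
            out[cid] = (f"P{p}", ROW_LETTERS[r], str(c))
        return out

    @property
    def n_pools(self) -> int:
        return len(self.pool_ids)


def build_pool_design(clones: Mapping[str, object]) -> PoolDesign:
    """Pool design from clone objects exposing plate/row/column attributes.

    Every clone must have a unique (plate, row, column) address; the design
    contains one pool per occupied plate plus the full 16 row pools and 24
    column pools.
    """
    addresses: dict[str, tuple[int, int, int]] = {}
    for cid, c in clones.items():
        addr = (int(c.plate), int(c.row), int(c.column))
        addresses[cid] = addr
    if len(set(addresses.values())) != len(addresses):
        raise ValueError("duplicate plate/row/column addresses in pool design")
    plates = sorted({p for p, _, _ in addresses.values()})
    pool_ids: list[str] = [f"P{p}" for p in plates]
    pool_ids += list(ROW_LETTERS)
    pool_ids += [str(c) for c in range(1, 25)]
    pool_axis = {f"P{p}": "plate" for p in plates}
    pool_axis.update({r: "row" for r in ROW_LETTERS})
    pool_axis.update({str(c): "column" for c in range(1, 25)})
    members: dict[str, list[str]] = {pid: [] for pid in pool_ids}
    for cid, (p, r, c) in addresses.items():
        members[f"P{p}"].append(cid)
        members[ROW_LETTERS[r]].append(cid)
        members[str(c)].append(cid)
    return PoolDesign(pool_ids, pool_axis, members, addresses)


@dataclass
class PoolCall:
    """Deconvolution result for one probe."""

    probe_id: str
    positive_pools: list[str]
    addresses: list[tuple[int, int, int]]
    clone_ids: list[str]
    status: str  # unambiguous | multi_consistent | unresolved
    n_positive_pools: int
    llr: float = 0.0


def estimate_threshold(intensities: np.ndarray, n_sd: float = 3.0) -> float:
    """Positivity threshold: background mean + ``n_sd`` background SDs.

    The background mode is estimated robustly from the lower half of the
    intensity distribution (median and MAD-derived sigma), so a minority of
    true positives does not bias it.
    """
    flat = np.asarray(intensities).ravel()
    lower = flat[flat <= np.median(flat)]
    mu = float(np.median(flat))
    sigma = float(1.4826 * np.median(np.abs(lower - mu)))
    if sigma == 0:
        sigma = float(np.std(flat)) or 1.0
    return mu + n_sd * sigma


def _gauss_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd * math.sqrt(2 * math.pi))


def deconvolve_pools(
    signals,
    design: PoolDesign,
    clone_set: Sequence[str] | None = None,
    intensity_threshold: float | None = None,
    signal_model: tuple[float, float, float, float] | None = None,
    graph=None,
) -> list[PoolCall]:
    """Invert pool signals to clone addresses.

    A pool is positive when its intensity reaches the threshold (default:
    background mean + 3 SD, estimated from the lower intensity mode).  A
    probe is resolvable when it has at least two positive pools and the
    product of the positive pools over the three axes, intersected with the
    clone set, yields exactly one clone (``unambiguous``) or a set of
    mutually overlapping clones (``multi_consistent``; requires ``graph``, an
    overlap graph, to verify the clones overlap).  A clone is consistent when
    all three of its pools are positive — with densely re-arrayed plates two
    positive pools constrain only two coordinates and cannot single out a
    well, so probes losing a pool to a false negative stay unresolved rather
    than being guessed.  Each candidate is scored by a two-component Gaussian
    log-likelihood ratio (signal vs background) summed over its three pools;
    the maximum-likelihood candidate must itself be pool-consistent.
    """
    intens = np.asarray(signals.intensities, dtype=float)
    if intens.shape[0] != design.n_pools:
        raise ValueError(
            f"signal matrix has {intens.shape[0]} pools, design has {design.n_pools}"
        )
    if intensity_threshold is None:
        intensity_threshold = estimate_threshold(intens)
    if signal_model is None:
        flat = intens.ravel()
        bg = flat[flat < intensity_threshold]
        sig = flat[flat >= intensity_threshold]
        mu0, sd0 = float(np.mean(bg)), float(np.std(bg) or 1.0)
        if sig.size >= 2:
            mu1, sd1 = float(np.mean(sig)), float(np.std(sig) or 1.0)
        else:
            mu1, sd1 = mu0 + 3.0, sd0
    else:
        mu0, sd0, mu1, sd1 = signal_model

    clones = (
        set(clone_set) if clone_set is not None else set(design.addresses)
    )
    pool_index = {pid: i for i, pid in enumerate(design.pool_ids)}
    clone_pools = design.clone_pools()

    calls: list[PoolCall] = []
    for j, probe in enumerate(signals.probe_ids):
        col = intens[:, j]
        pos_idx = np.nonzero(col >= intensity_threshold)[0]
        pos_ids = [design.pool_ids[i] for i in pos_idx]
        if len(pos_ids) < 2:
            calls.append(PoolCall(probe, pos_ids, [], [], "unresolved", len(pos_ids)))
            continue
        pos_set = set(pos_ids)
        llr_pool = _gauss_logpdf(col, mu1, sd1) - _gauss_logpdf(col, mu0, sd0)
        candidates: list[tuple[float, str]] = []
        for cid in clones:
            if cid not in clone_pools:
                continue
            trio = clone_pools[cid]
            if any(pid not in pos_set for pid in trio):
                continue
            score = float(sum(llr_pool[pool_index[pid]] for pid in trio))
            candidates.append((score, cid))
        if not candidates:
            calls.append(PoolCall(probe, pos_ids, [], [], "unresolved", len(pos_ids)))
            continue
        candidates.sort(key=lambda t: (-t[0], t[1]))
        best_llr, best = candidates[0]
        chosen = [cid for _, cid in candidates]
        if len(chosen) == 1:
            status = "unambiguous"
        else:
            overlapping = graph is not None and all(
                graph.has_edge(a, b) or a == b
                for a, b in itertools.combinations(chosen, 2)
            )
            status = "multi_consistent" if overlapping else "unresolved"
            if status == "unresolved":
                chosen = []
        calls.append(
            PoolCall(
                probe,
                pos_ids,
                [design.addresses[cid] for cid in chosen],
                chosen,
                status,
                len(pos_ids),
                best_llr,
            )
        )
    return calls


def chance_positive_prob(design: PoolDesign | int, f: float) -> float:
    """Probability that a probe with no true clone reaches >= 2 positive pools.

    With K pools and independent per-pool false-positive rate ``f``:
    ``P = 1 - (1-f)^K - K f (1-f)^(K-1)``.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("false-positive rate must be in [0, 1]")
    k = design if isinstance(design, int) else design.n_pools
    if f == 1.0:
        return 1.0
    q = math.log1p(-f)
    p0 = math.exp(k * q)
    p1 = k * f * math.exp((k - 1) * q)
    return 1.0 - p0 - p1
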