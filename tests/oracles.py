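"""Independent oracles used by the tests.

The exhaustive assignment oracle enumerates every one-to-one subset of
candidate peak pairs by depth-first search — no assignment solver involved —
and is only feasible for small spectra (≤ 6 peaks or so).
"""
from __future__ import annotations

import numpy as np

from photonet.networking import match_peaks
from photonet.types import FragmentSpectrum


def exhaustive_modified_cosine(
    a: FragmentSpectrum, b: FragmentSpectrum, frag_tol: float
) -> tuple[float, int]:
    """Modified cosine by brute-force enumeration of all peak matchings."""
    pairs = match_peaks(a, b, frag_tol)
    # collapse duplicate (i, j) cells to their best weight, as a matching
    # uses each cell at most once
    cells: dict[tuple[int, int], float] = {}
    for p in pairs:
        key = (p.index_a, p.index_b)
        cells[key] = max(cells.get(key, 0.0), p.weight)
    items = sorted(cells.items())

    best = {"total": 0.0, "count": 0}

    def dfs(k: int, used_a: frozenset, used_b: frozenset, total: float, count: int):
        if total > best["total"] + 1e-15 or (
            abs(total - best["total"]) <= 1e-15 and count > best["count"]
        ):
            best["total"], best["count"] = total, count
        if k == len(items):
            return
        (i, j), w = items[k]
        if i not in used_a and j not in used_b:
            dfs(k + 1, used_a | {i}, used_b | {j}, total + w, count + 1)
        dfs(k + 1, used_a, used_b, total, count)

    dfs(0, frozenset(), frozenset(), 0.0, 0)
    norm = float(np.sqrt(a.intensities.sum()) * np.sqrt(b.intensities.sum()))
    if norm == 0.0 or not items:
        return 0.0, 0
    return min(best["total"] / norm, 1.0), best["count"]


def random_related_pair(
    rng: np.random.Generator, frag_tol: float = 0.02, max_peaks: int = 6
) -> tuple[FragmentSpectrum, FragmentSpectrum]:
    """A pair of small spectra engineered to produce assignment conflicts.

    Peaks of b are drawn as near-copies of a's peaks, shifted near-copies
    (by the precursor mass difference), or fresh — so single peaks often
    carry both direct and shifted candidates, the regime where a greedy
    assignment can be suboptimal.
    """
    a = random_small_spectrum(rng, max_peaks, "a")
    delta = float(rng.uniform(5.0, 40.0))
    n_b = int(rng.integers(1, max_peaks + 1))
    mz_b = []
    for _ in range(n_b):
        mode = rng.integers(0, 3)
        src = float(rng.choice(a.mz))
        jitter = float(rng.uniform(-frag_tol, frag_tol)) * 0.8
        if mode == 0:
            mz_b.append(src + jitter)
        elif mode == 1:
            mz_b.append(src + delta + jitter)
        else:
            mz_b.append(float(rng.uniform(80.0, 400.0)))
    mz_b = np.array(sorted(mz_b))
    while np.any(np.diff(mz_b) <= 0):
        mz_b = mz_b + np.concatenate([[0.0], np.cumsum(np.diff(mz_b) <= 0) * 1e-4])
        mz_b = np.array(sorted(mz_b))
    b = FragmentSpectrum(
        feature_id="b",
        precursor_mz=a.precursor_mz + delta,
        rt=1.0,
        mz=mz_b,
        intensities=rng.uniform(0.1, 100.0, size=n_b),
    )
    return a, b


def random_small_spectrum(
    rng: np.random.Generator, max_peaks: int = 6, feature_id: str = "q"
) -> FragmentSpectrum:
    """A random spectrum with ≤ max_peaks peaks for fuzzing the oracle."""
    n = int(rng.integers(1, max_peaks + 1))
    mz = np.sort(rng.uniform(80.0, 400.0, size=n))
    while np.any(np.diff(mz) < 0.05):
        mz = np.sort(rng.uniform(80.0, 400.0, size=n))
    intensities = rng.uniform(0.1, 100.0, size=n)
    precursor = float(mz.max() + rng.uniform(10.0, 60.0))
    return FragmentSpectrum(
        feature_id=feature_id, precursor_mz=precursor, rt=1.0, mz=mz, intensities=intensities
    )
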