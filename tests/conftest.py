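"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths used by the package:
connected components are found by breadth-first flood fill, border
distances by exhaustive pairwise pixel distances, and Mann-Whitney
p-values by enumerating label arrangements.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import blebquant as bq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# ---------------------------------------------------------------------------
# independent oracles


def flood_fill_components(binary: np.ndarray) -> list[list[tuple[int, int]]]:
    """8-connected components by BFS flood fill (no scipy/skimage)."""
    h, w = binary.shape
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for r in range(h):
        for c in range(w):
            if not binary[r, c] or seen[r, c]:
                continue
            comp = []
            q = deque([(r, c)])
            seen[r, c] = True
            while q:
                cr, cc = q.popleft()
                comp.append((cr, cc))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and binary[nr, nc] and not seen[nr, nc]:
                            seen[nr, nc] = True
                            q.append((nr, nc))
            comps.append(comp)
    return comps


def oracle_puncta_counts(
    cc3: np.ndarray,
    ring_owner: np.ndarray,
    threshold: float,
    min_area_um2: float,
    max_area_um2: float,
    mpp: float,
) -> dict[int, int]:
    """Brute-force spot oracle: threshold -> flood fill -> area filter.

    Replicates the punctum-to-cell assignment contract (ring owner at the
    rounded centroid, falling back to the majority owner among pixels).
    """
    masked = np.where(ring_owner > 0, np.asarray(cc3, dtype=float), 0.0)
    comps = flood_fill_components(masked > threshold)
    counts: dict[int, int] = {}
    px_area = mpp**2
    for comp in comps:
        area = len(comp) * px_area
        if not min_area_um2 <= area <= max_area_um2:
            continue
        cr = sum(p[0] for p in comp) / len(comp)
        cc = sum(p[1] for p in comp) / len(comp)
        owner = int(ring_owner[int(round(cr)), int(round(cc))])
        if owner == 0:
            votes: dict[int, int] = {}
            for r, c in comp:
                o = int(ring_owner[r, c])
                if o > 0:
                    votes[o] = votes.get(o, 0) + 1
            owner = min((k for k, v in votes.items() if v == max(votes.values())))
        counts[owner] = counts.get(owner, 0) + 1
    return counts


def oracle_ring_sets(
    labels: np.ndarray, width_px: float
) -> dict[int, set[tuple[int, int]]]:
    """Exhaustive ring oracle: per-pixel min distance to every nucleus.

    A background pixel joins the ring of the nucleus with the smallest
    border distance (ties to the lower label) when that distance is at
    most ``width_px``.
    """
    ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    nuc_px = {lab: np.argwhere(labels == lab).astype(float) for lab in ids}
    rings: dict[int, set[tuple[int, int]]] = {lab: set() for lab in ids}
    h, w = labels.shape
    for r in range(h):
        for c in range(w):
            if labels[r, c] != 0:
                continue
            best_lab, best_d = 0, math.inf
            for lab in ids:
                d2 = ((nuc_px[lab] - (r, c)) ** 2).sum(axis=1).min()
                d = math.sqrt(d2)
                if d < best_d:
                    best_d, best_lab = d, lab
            if best_lab and best_d <= width_px:
                rings[best_lab].add((r, c))
    return rings


def oracle_mannwhitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating label arrangements."""
    a, b = list(a), list(b)
    pooled = a + b
    n, na = len(pooled), len(a)

    def u_stat(ix):
        xa = [pooled[i] for i in ix]
        xb = [pooled[i] for i in range(n) if i not in set(ix)]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in xa for y in xb
        )

    u_obs = u_stat(tuple(range(na)))
    nb = n - na
    lo, hi = min(u_obs, na * nb - u_obs), max(u_obs, na * nb - u_obs)
    count = 0
    total = 0
    for ix in itertools.combinations(range(n), na):
        u = u_stat(ix)
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# fixtures


def disk_labels(shape, centers, radii) -> np.ndarray:
    """Label map of disks (pixel-centre inclusion), labelled 1..n in order."""
    labels = np.zeros(shape, dtype=np.int32)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, ((r0, c0), rad) in enumerate(zip(centers, radii), start=1):
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = i
    return labels


@pytest.fixture(scope="session")
def default_field():
    """A mid-density synthetic field with all phenotypes present."""
    cfg = bq.SyntheticConfig(
        n_cells=300,
        field_px=(800, 800),
        frac_gh2ax=0.2,
        frac_bleb=0.2,
        frac_coloc=0.1,
        frac_diffuse_cc3=0.3,
        seed=42,
    )
    return bq.generate_field(cfg, field_id="default_fixture")


@pytest.fixture(scope="session")
def analyzed_default(default_field):
    field, _truth = default_field
    return bq.analyze_field(field)


def match_to_truth(label_map, truth, tol_px: float):
    """Greedy centroid matching of segmented nuclei to ground truth."""
    t_ids = sorted(truth.centroids)
    t_xy = np.array([truth.centroids[i] for i in t_ids])
    matches = {}
    used = set()
    for lab in label_map.label_ids:
        c = np.array(label_map.centroids[lab])
        d = np.sqrt(((t_xy - c) ** 2).sum(axis=1))
        order = np.argsort(d)
        for j in order:
            if d[j] > tol_px:
                break
            if t_ids[j] not in used:
                matches[lab] = t_ids[j]
                used.add(t_ids[j])
                break
    return matches
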