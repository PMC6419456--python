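"""Shared fixtures and the brute-force TM-score oracle.

The oracle enumerates every sequence-order-preserving correspondence of size
>= 5 between two bead chains, rigidly superposes each matched set (Kabsch,
reflection allowed), and takes the best TM sum — independent of the
production search, feasible for chains of ~10 beads.
"""

import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tadfamily.structsim as ss

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def brute_force_tm(a: np.ndarray, b: np.ndarray, min_k: int = 5) -> float:
    ca = ss._normalize_scale(np.asarray(a, float))
    cb = ss._normalize_scale(np.asarray(b, float))
    la, lb = len(ca), len(cb)
    lmin = min(la, lb)
    d0 = ss.d0_from_length(lmin)
    best = 0.0
    for k in range(min_k, lmin + 1):
        ia_all = np.array(list(itertools.combinations(range(la), k)))
        ib_all = np.array(list(itertools.combinations(range(lb), k)))
        A = ca[ia_all]
        B = cb[ib_all]
        Ac = A - A.mean(axis=1, keepdims=True)
        Bc = B - B.mean(axis=1, keepdims=True)
        na, nb = len(ia_all), len(ib_all)
        chunk = max(1, 2_000_000 // max(1, k * nb))
        for s0 in range(0, na, chunk):
            Acs = Ac[s0 : s0 + chunk]
            h = np.einsum("akd,bke->abde", Acs, Bc)
            u, _, vt = np.linalg.svd(h)
            # rotation (reflection allowed) = V U^T for each pair
            rot = np.einsum("abed,abfe->abdf", vt, u)
            moved = np.einsum("akd,abed->abke", Acs, rot)
            dist = np.linalg.norm(moved - Bc[None], axis=3)
            score = (1.0 / (1.0 + (dist / d0) ** 2)).sum(axis=2) / lmin
            best = max(best, float(score.max()))
    return min(best, 1.0)


@pytest.fixture(scope="session")
def tm_oracle():
    return brute_force_tm


@pytest.fixture
def rng():
    return np.random.default_rng(0)
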