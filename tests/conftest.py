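"""Shared fixtures: synthetic records and independent brute-force oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ecgkit import synth
from ecgkit.denoise import NLMConfig


@pytest.fixture(scope="session")
def clean_record():
    """Default sinus-rhythm 10 s, 500 Hz record with exact R-peak truth."""
    return synth.generate_clean_record(seed=42, record_id="CLEAN42")


@pytest.fixture(scope="session")
def clean_60bpm():
    rhythm = synth.RhythmSpec(mean_hr_bpm=60.0, rr_model="constant", rr_sd_s=0.0)
    return synth.generate_clean_record(rhythm=rhythm, seed=7, record_id="SIXTY")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# independent oracles (deliberately literal / brute-force)

def nlm_oracle(d: np.ndarray, cfg: NLMConfig) -> np.ndarray:
    """Literal triple-loop weighted-average evaluation of the NLM equations,
    with the documented boundary rule (offsets valid for both patches)."""
    d = np.asarray(d, dtype=float)
    n = d.size
    h, search = cfg.patch_half_width, cfg.search_half_width
    g = cfg.kernel_weights()
    lam = cfg.lambda_uv
    assert lam is not None and lam > 0
    out = np.empty(n)
    for i in range(n):
        num = den = 0.0
        for j in range(max(0, i - search), min(n, i + search + 1)):
            dist2 = mass = 0.0
            for q, delta in enumerate(range(-h, h + 1)):
                if 0 <= i + delta < n and 0 <= j + delta < n:
                    dist2 += g[q] * (d[i + delta] - d[j + delta]) ** 2
                    mass += g[q]
            w = math.exp(-dist2 / (2.0 * mass * lam * lam))
            num += w * d[j]
            den += w
        out[i] = num / den
    return out


def extrema_oracle(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Neighbor-scan extrema with the left-center plateau rule."""
    x = np.asarray(x, dtype=float)
    n = x.size

    def peaks_of(sig):
        found = []
        i = 1
        while i < n - 1:
            if sig[i] > sig[i - 1]:
                j = i
                while j < n - 1 and sig[j + 1] == sig[i]:
                    j += 1
                if j < n - 1 and sig[j + 1] < sig[i]:
                    found.append((i + j) // 2)
                i = j + 1
            else:
                i += 1
        return found

    return peaks_of(x), peaks_of(-x)


def prominence_oracle(x: np.ndarray, index: int) -> float:
    """Contour-line scan: walk out to the nearest strictly higher sample on
    each side (or the edge); base = the higher of the two interval minima."""
    x = np.asarray(x, dtype=float)
    n = x.size
    h = x[index]
    left_min = h
    for k in range(index - 1, -1, -1):
        if x[k] > h:
            break
        left_min = min(left_min, x[k])
    right_min = h
    for k in range(index + 1, n):
        if x[k] > h:
            break
        right_min = min(right_min, x[k])
    return h - max(left_min, right_min)
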