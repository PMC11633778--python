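import numpy as np
import pytest
from scipy.ndimage import distance_transform_edt

import notchscreen as ns
from notchscreen import synthdata as sd


def match_f1(truth: np.ndarray, rec: np.ndarray) -> float:
    """Object-count F1 with objects matched by IoU > 0.5."""
    tids = [i for i in np.unique(truth) if i]
    rids = [i for i in np.unique(rec) if i]
    matched = 0
    for t in tids:
        tm = truth == t
        labs, cnt = np.unique(rec[tm], return_counts=True)
        lab = labs[np.argmax(cnt)]
        if lab == 0:
            continue
        rm = rec == lab
        if (tm & rm).sum() / (tm | rm).sum() > 0.5:
            matched += 1
    p = matched / max(len(rids), 1)
    r = matched / max(len(tids), 1)
    return 2 * p * r / max(p + r, 1e-9)


def boundary_distance(truth: np.ndarray, rec: np.ndarray) -> float:
    """Mean symmetric distance between label-boundary pixels."""

    def bnd(lab):
        b = np.zeros(lab.shape, bool)
        for ax in (0, 1):
            nb = np.roll(lab, 1, axis=ax)
            b |= (nb != lab) & ((lab > 0) | (nb > 0))
        return b

    tb, rb = bnd(truth), bnd(rec)
    if not tb.any() or not rb.any():
        return np.nan
    d1 = distance_transform_edt(~rb)[tb].mean()
    d2 = distance_transform_edt(~tb)[rb].mean()
    return 0.5 * (d1 + d2)


def render_spot_image(
    points: np.ndarray,
    shape=(512, 512),
    amplitude: float = 800.0,
    sigma: float = 1.2,
    background: float = 100.0,
    seed: int = 0,
) -> np.ndarray:
    """Plant Gaussian puncta at the given (y, x) points on a noisy background."""
    img = np.full(shape, background)
    half = 8
    for y, x in points:
        r0, c0 = int(round(y)) - half, int(round(x)) - half
        r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r1, shape[0]), min(c1, shape[1])
        rr, cc = np.mgrid[r0c:r1c, c0c:c1c]
        img[r0c:r1c, c0c:c1c] += amplitude * np.exp(
            -((rr - y) ** 2 + (cc - x) ** 2) / (2 * sigma**2)
        )
    rng = np.random.default_rng(seed)
    return rng.poisson(img).astype(float)


@pytest.fixture(scope="session")
def default_field():
    """One rendered NT-like field reused by read-only tests."""
    return sd.render_field(sd.NT_LIKE, 25, seed=11)


@pytest.fixture(scope="session")
def segmented_field(default_field):
    img = ns.FieldImage.from_synthetic(default_field)
    seg, flags = ns.segment_field(img)
    return default_field, img, seg, flags
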