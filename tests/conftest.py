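import numpy as np
import pytest

from atlasparc import PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(shape=(32, 32, 32), n_structures_per_hemisphere=3, seed=11)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(image, labels, brain mask) of a 32^3 six-structure phantom."""
    return make_phantom(small_spec)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Four mildly deformed subjects of the small phantom."""
    return make_cohort(small_spec, 4, deformation_sd=0.5, seed=21)


@pytest.fixture(scope="session")
def identical_cohort(small_spec):
    """Four bit-identical subjects (deformation SD 0)."""
    return make_cohort(small_spec, 4, deformation_sd=0.0, seed=22)


def gaussian_smooth_oracle(img: np.ndarray, sigma: float,
                           truncate: float = 4.0) -> np.ndarray:
    """Brute-force separable discrete Gaussian smoothing, symmetric edges.

    Independent of scipy.ndimage: explicit kernel construction and shifted
    sums over a padded array.
    """
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    w /= w.sum()
    out = img.astype(np.float64)
    for ax in range(img.ndim):
        pad = [(0, 0)] * img.ndim
        pad[ax] = (r, r)
        p = np.pad(out, pad, mode="symmetric")
        acc = np.zeros_like(out)
        for k in range(2 * r + 1):
            sl = [slice(None)] * img.ndim
            sl[ax] = slice(k, k + img.shape[ax])
            acc += w[k] * p[tuple(sl)]
        out = acc
    return out


def lncc_oracle(a: np.ndarray, b: np.ndarray, sigma: float) -> np.ndarray:
    """Windowed weighted-correlation oracle for the LNCC map."""
    mu_a = gaussian_smooth_oracle(a, sigma)
    mu_b = gaussian_smooth_oracle(b, sigma)
    va = gaussian_smooth_oracle(a * a, sigma) - mu_a**2
    vb = gaussian_smooth_oracle(b * b, sigma) - mu_b**2
    cov = gaussian_smooth_oracle(a * b, sigma) - mu_a * mu_b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cov / np.sqrt(np.clip(va, 0, None) * np.clip(vb, 0, None))
    out = np.clip(out, -1, 1)
    out[(va < 1e-6 * a.var()) | (vb < 1e-6 * b.var())] = 0.0
    return out


def bh_oracle(pvals: np.ndarray, q: float) -> np.ndarray:
    """Brute-force Benjamini-Hochberg: reject p_(1..k*) where
    k* = max{ k : p_(k) <= k q / m }."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    flags = np.zeros(m, dtype=bool)
    kstar = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            kstar = k
    flags[order[:kstar]] = True
    return flags
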