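"""Automatic scree-plot elbow selection (Zhu & Ghodsi profile likelihood).

The embedding dimension for both feature families is chosen from the scree
plot of singular values.  The first "elbow" is the split point that
maximizes a two-piece Gaussian profile likelihood with pooled variance:
values before the elbow and after it are each modelled as i.i.d. normal with
their own mean and a shared variance.  Subsequent elbows are found by
recursing on the values after the previous elbow; the embeddings here use
the second elbow by default.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["zhu_ghodsi_dimension", "profile_log_likelihoods"]


def profile_log_likelihoods(values: np.ndarray) -> np.ndarray:
    """Log-likelihood of each candidate split point ``q = 1..n``.

    ``values`` must be sorted non-increasing.  Entry ``q-1`` is the profile
    log-likelihood of modelling ``values[:q]`` and ``values[q:]`` as two
    Gaussian groups with pooled variance.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    lls = np.empty(n)
    for q in range(1, n + 1):
        s1, s2 = v[:q], v[q:]
        mu1 = s1.mean()
        mu2 = s2.mean() if s2.size else 0.0
        ss = ((s1 - mu1) ** 2).sum() + ((s2 - mu2) ** 2).sum()
        denom = n - 1 - (1 if q < n else 0)
        sigma = np.sqrt(ss / denom) if denom > 0 else 0.0
        sigma = max(sigma, 1e-12)
        lls[q - 1] = norm.logpdf(s1, mu1, sigma).sum()
        if s2.size:
            lls[q - 1] += norm.logpdf(s2, mu2, sigma).sum()
    return lls


def _first_elbow(values: np.ndarray) -> int:
    return int(np.argmax(profile_log_likelihoods(values))) + 1


def zhu_ghodsi_dimension(values, n_elbows: int = 1) -> int:
    """Number of values retained at the ``n_elbows``-th scree elbow.

    Parameters
    ----------
    values : sequence of float
        Singular (or eigen-) values, sorted non-increasing, positive.
    n_elbows : int
        Which elbow to return; 2 gives the "second elbow" used for the
        embedding dimensions here.

    Returns
    -------
    int
        1-based count of retained values.  If an elbow exhausts the
        sequence, recursion stops and the full length is returned.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("need a 1-D sequence of at least 3 values")
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("values must be sorted non-increasing")
    if n_elbows < 1:
        raise ValueError("n_elbows must be >= 1")
    elbow = _first_elbow(v)
    for _ in range(n_elbows - 1):
        suffix = v[elbow:]
        if suffix.size == 0:
            break
        elbow += _first_elbow(suffix) if suffix.size > 1 else 1
    return int(min(elbow, len(v)))


def select_dimension(singular_values: np.ndarray, n_elbows: int = 2) -> int:
    """Embedding dimension from a raw singular-value vector.

    Discards numerically-zero trailing values (relative threshold 1e-10)
    before elbow selection; degenerate spectra with fewer than 3 positive
    values keep all of them.
    """
    s = np.asarray(singular_values, dtype=float)
    s = s[s > s.max() * 1e-10] if s.size and s.max() > 0 else s
    if len(s) < 3:
        return max(1, len(s))
    return zhu_ghodsi_dimension(s, n_elbows=n_elbows)
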