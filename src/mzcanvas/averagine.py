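"""Averagine isotope-pattern model (Poisson approximation).

Peptide isotope envelopes are predicted from neutral mass alone using the
"averagine" average amino-acid composition (C4.9384 H7.7583 N1.3577 O1.4773
S0.0417, 111.1254 Da per residue). The expected number of heavy-isotope
incorporations grows linearly with mass; the resulting abundance pattern is
well approximated by a Poisson distribution over the isotope index, which is
what envelope scoring and the synthetic generator share.
"""

from __future__ import annotations

import numpy as np

#: Expected heavy-isotope count per Da of neutral mass for averagine
#: (13C, 15N, 2H, 17O, 33S single-substitution probabilities combined).
_LAMBDA_PER_DA = 5.363e-4


def isotope_distribution(neutral_mass: float, n_isotopes: int = 6) -> np.ndarray:
    """Relative abundances of isotopes 0..n−1, normalized to sum to 1."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    if n_isotopes < 1:
        raise ValueError("need at least one isotope")
    lam = _LAMBDA_PER_DA * neutral_mass
    k = np.arange(n_isotopes)
    # Poisson pmf in log space: exp(-lam) lam^k / k!
    logp = -lam + k * np.log(lam) - np.cumsum(np.log(np.maximum(k, 1)))
    p = np.exp(logp)
    return p / p.sum()


def envelope_cosine(observed: np.ndarray, neutral_mass: float) -> float:
    """Cosine similarity between observed isotope intensities and the
    averagine prediction at this mass; in [0, 1] for non-negative input."""
    obs = np.asarray(observed, dtype=float)
    pred = isotope_distribution(neutral_mass, obs.size)
    denom = np.linalg.norm(obs) * np.linalg.norm(pred)
    if denom == 0:
        return 0.0
    return float(np.dot(obs, pred) / denom)
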