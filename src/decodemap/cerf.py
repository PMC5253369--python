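"""Contrast event-related field (cERF) heuristic and activation patterns.

The true discriminative map of a decoding problem is unknown on real data.
For evoked (time-locked) MEG the contrast ERF — the normalized difference
of the condition-wise trial averages — is a neurophysiologically plausible
stand-in: for balanced, feature-centered data it is collinear with the
activation pattern A = Sigma_X w_LS of the least-squares decoder, i.e. with
the generative-model equivalent of the discriminative weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decoding import EpochedDataset
from .maps import (
    DegenerateMapError,
    InterpretabilityReport,
    MapEnsemble,
    MultivariateBrainMap,
    interpretability,
    normalize_map,
)

__all__ = ["CerfMap", "compute_cerf", "activation_pattern", "approx_metrics"]


@dataclass(frozen=True)
class CerfMap:
    """cERF map with the class means and counts it was computed from."""

    map: MultivariateBrainMap
    class_mean_pos: np.ndarray
    class_mean_neg: np.ndarray
    n_pos: int
    n_neg: int


def compute_cerf(data: EpochedDataset) -> CerfMap:
    """Unit-normalized difference of class mean trials.

    Raises
    ------
    ValueError
        If only one class is present (the contrast needs both conditions;
        multiclass problems should be binarized upstream).
    DegenerateMapError
        If the class means coincide exactly.
    """
    pos = data.labels == 1
    neg = data.labels == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cERF needs trials from both classes (+1 and -1)")
    mean_pos = data.trials[pos].mean(axis=0)
    mean_neg = data.trials[neg].mean(axis=0)
    diff = mean_pos - mean_neg
    if np.linalg.norm(diff) == 0.0:
        raise DegenerateMapError("class means coincide; cERF undefined")
    return CerfMap(
        map=normalize_map(diff),
        class_mean_pos=mean_pos,
        class_mean_neg=mean_neg,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def activation_pattern(data: EpochedDataset, decoder_weights):
    """Activation pattern A = Sigma_X w of a linear decoder.

    Multiplying the empirical feature covariance (pooled over all trials,
    mean-removed, denominator n-1) by the decoder weights converts the
    discriminative ("backward") weight vector into its generative
    ("forward") counterpart.  Returns ``(A, A_normalized)``.
    """
    w = np.asarray(decoder_weights, float)
    if w.shape != (data.p,):
        raise ValueError(
            f"decoder weights must have length p={data.p}, got {w.shape}"
        )
    if data.n < 2:
        raise ValueError("need at least 2 trials for a covariance")
    Xc = data.trials - data.trials.mean(axis=0)
    # covariance-vector product without forming the p x p matrix
    A = Xc.T @ (Xc @ w) / (data.n - 1)
    return A, normalize_map(A)


def approx_metrics(ensemble: MapEnsemble, cerf: CerfMap) -> InterpretabilityReport:
    """Heuristic interpretability metrics with the cERF map as reference.

    eta_tilde is the mean cosine of ensemble members to the cERF map and
    beta_tilde the absolute cosine of the main map to it; the decomposition
    eta_tilde = beta_tilde * psi holds exactly in the sign-consistent
    regime, mirroring the exact-reference case.
    """
    return interpretability(ensemble, cerf.map)
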