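"""Out-of-bag model selection balancing accuracy and interpretability.

For every candidate regularization strength lambda, the decoder is refit on
m bootstrap replicates of the training set; each replicate is validated on
its out-of-bag (OOB) trials.  The OOB prediction events give the expected
prediction error EPE (0/1 loss) with a bias-variance decomposition, hence
the performance delta = 1 - EPE; the replicate weight maps give the
interpretability metrics against a reference map (cERF by default).  The
two objectives are folded into one Pareto-scalarized criterion

    zeta = (w1 * eta_tilde + w2 * delta) / (w1 + w2)   if delta >= kappa
    zeta = 0                                           otherwise

and the grid value maximizing zeta is selected (ties broken toward larger
lambda, i.e. the sparser model).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .cerf import CerfMap, compute_cerf
from .decoding import EpochedDataset, Standardizer, fit_lasso
from .maps import (
    DegenerateMapError,
    MapEnsemble,
    MultivariateBrainMap,
    interpretability,
    normalize_map,
)

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "PerturbationPlan",
    "LambdaEvaluation",
    "ModelSelectionTable",
    "oob_partitions",
    "epe_bias_variance",
    "scalarize",
    "evaluate_lambda",
    "select_model",
]

#: regularization grid used throughout the validation studies
DEFAULT_LAMBDA_GRID = (0.001, 0.01, 0.1, 1.0, 10.0, 50.0, 100.0, 250.0,
                       500.0, 1000.0)


@dataclass(frozen=True)
class PerturbationPlan:
    """m bootstrap in-bag/out-of-bag index partitions of n trials."""

    n: int
    m: int
    seed: int
    partitions: tuple  # of (in_bag ndarray size n, oob ndarray) pairs
    scheme: str = "bootstrap-oob"

    def __post_init__(self) -> None:
        if len(self.partitions) != self.m:
            raise ValueError("plan must hold exactly m partitions")
        for in_bag, oob in self.partitions:
            if len(in_bag) != self.n:
                raise ValueError("in-bag draws must have size n")
            if len(oob) == 0:
                raise ValueError("out-of-bag sets must be nonempty")


def oob_partitions(n: int, m: int, seed: int) -> PerturbationPlan:
    """Draw m with-replacement bootstrap samples of size n with OOB complements.

    A draw that happens to cover every trial (possible at tiny n) is
    redrawn so that each replicate has a nonempty validation set.  The same
    seed reproduces the plan bit-exactly.
    """
    if n < 2:
        raise ValueError("need at least 2 trials")
    if m < 1:
        raise ValueError("m must be positive")
    rng = np.random.default_rng(seed)
    parts = []
    all_idx = np.arange(n)
    for _ in range(m):
        while True:
            in_bag = rng.integers(0, n, size=n)
            mask = np.ones(n, dtype=bool)
            mask[in_bag] = False
            oob = all_idx[mask]
            if oob.size > 0:
                break
        parts.append((in_bag, oob))
    return PerturbationPlan(n=n, m=m, seed=int(seed), partitions=tuple(parts))


def epe_bias_variance(oob_predictions: Sequence[Sequence[int]], truth):
    """EPE with 0/1-loss bias-variance decomposition over OOB predictions.

    Parameters
    ----------
    oob_predictions : sequence of length n
        For each trial, the -1/+1 predictions it received across the
        replicates in which it was out-of-bag.  Every trial must appear at
        least once.
    truth : array of length n
        True -1/+1 labels.

    Returns
    -------
    (epe, bias, variance) : floats
        Per trial, the *main prediction* is the majority vote of its OOB
        predictions (tie -> +1); its bias is the 0/1 loss of that main
        prediction and its variance the fraction of its predictions that
        disagree with it.  EPE is the mean 0/1 loss pooled over all OOB
        prediction events; aggregate bias and variance are plain means over
        trials.
    """
    truth = np.asarray(truth)
    n = truth.size
    if len(oob_predictions) != n:
        raise ValueError("need one prediction list per trial")
    biases = np.empty(n)
    variances = np.empty(n)
    total_loss = 0.0
    total_events = 0
    for i in range(n):
        preds = np.asarray(oob_predictions[i])
        if preds.size == 0:
            raise ValueError(
                f"trial {i} was never out-of-bag; increase m"
            )
        main = 1 if preds.sum() >= 0 else -1
        biases[i] = float(main != truth[i])
        variances[i] = float(np.mean(preds != main))
        total_loss += float(np.sum(preds != truth[i]))
        total_events += preds.size
    epe = total_loss / total_events
    return epe, float(np.mean(biases)), float(np.mean(variances))


def scalarize(eta_tilde: float, delta: float, omega1: float = 1.0,
              omega2: float = 1.0, kappa: float = 0.6) -> float:
    """Pareto scalarization of interpretability and performance.

    Returns the omega-weighted average of ``eta_tilde`` and ``delta`` when
    the performance clears the admissibility threshold ``kappa`` (chance
    level plus a safety margin), and 0 otherwise.
    """
    if omega1 < 0 or omega2 < 0 or (omega1 == 0 and omega2 == 0):
        raise ValueError("weights must be nonnegative and not both zero")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    if delta < kappa:
        return 0.0
    return (omega1 * eta_tilde + omega2 * delta) / (omega1 + omega2)


@dataclass(frozen=True)
class LambdaEvaluation:
    """All quantities recorded for one grid value of lambda."""

    lam: float
    delta: float
    epe: float
    bias: float
    variance: float
    psi: float
    beta_tilde: float
    eta_tilde: float
    zeta: float
    ensemble: Optional[MapEnsemble]
    degenerate_count: int
    eta_true: float = math.nan  # vs a known ground-truth map, when given
    full_map: Optional[MultivariateBrainMap] = None  # fit on the full data

    @property
    def m_effective(self) -> int:
        return self.ensemble.m if self.ensemble is not None else 0


@dataclass(frozen=True)
class ModelSelectionTable:
    """One LambdaEvaluation per grid value plus the selected lambda.

    When every zeta is 0 (no model clears the performance threshold) the
    result is flagged inadmissible and ``chosen_lambda`` is None;
    ``advisory_lambda`` then carries the delta-argmax as a fallback hint.
    """

    rows: tuple
    chosen_lambda: Optional[float]
    admissible: bool
    advisory_lambda: float
    config: dict = field(default_factory=dict)

    def row(self, lam: float) -> LambdaEvaluation:
        for r in self.rows:
            if r.lam == lam:
                return r
        raise KeyError(f"lambda {lam} not in table")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "lambda": r.lam,
                    "delta": r.delta,
                    "epe": r.epe,
                    "bias": r.bias,
                    "variance": r.variance,
                    "psi": r.psi,
                    "beta_tilde": r.beta_tilde,
                    "eta_tilde": r.eta_tilde,
                    "zeta": r.zeta,
                    "eta_true": r.eta_true,
                    "degenerate_count": r.degenerate_count,
                    "m_effective": r.m_effective,
                }
                for r in self.rows
            ]
        )


def _as_reference_map(reference) -> MultivariateBrainMap:
    if isinstance(reference, CerfMap):
        return reference.map
    if isinstance(reference, MultivariateBrainMap):
        return reference
    return normalize_map(np.asarray(reference, float))


def _run_grid(
    data: EpochedDataset,
    grid: Sequence[float],
    plan: PerturbationPlan,
    *,
    standardize: bool = True,
):
    """Fit the whole lambda grid on every bootstrap replicate.

    Returns per-lambda raw weight maps (possibly all-zero) and per-trial
    OOB predictions.  One plan is shared across the grid, which lets each
    replicate warm-start coordinate descent along the (descending) lambda
    path and keeps the grid comparison free of partition noise.
    """
    lams_desc = sorted(set(float(l) for l in grid), reverse=True)
    n = data.n
    raw_maps = {lam: [] for lam in lams_desc}
    preds = {lam: [[] for _ in range(n)] for lam in lams_desc}
    for in_bag, oob in plan.partitions:
        train = data.subset(in_bag)
        X_oob = data.trials[oob]
        coef = None
        for lam in lams_desc:
            dec = fit_lasso(train, lam, standardize=standardize,
                            warm_start_coef=coef)
            coef = dec.std_weights
            raw_maps[lam].append(dec.raw_weights)
            scores = X_oob @ dec.raw_weights + dec.intercept
            yhat = np.where(scores >= 0.0, 1, -1)
            for k, i in enumerate(oob):
                preds[lam][i].append(int(yhat[k]))
    return raw_maps, preds


def _evaluate_from_runs(
    lam: float,
    raw_maps,
    oob_preds,
    truth,
    reference: MultivariateBrainMap,
    *,
    omega1: float,
    omega2: float,
    kappa: float,
    true_map: Optional[MultivariateBrainMap],
    provenance: dict,
    full_map: Optional[MultivariateBrainMap],
) -> LambdaEvaluation:
    # trials that never landed out-of-bag (possible at small m) simply
    # contribute no prediction events; the decomposition runs on the rest
    covered = [i for i, pr in enumerate(oob_preds) if len(pr) > 0]
    epe, bias, variance = epe_bias_variance(
        [oob_preds[i] for i in covered], np.asarray(truth)[covered]
    )
    delta = 1.0 - epe

    members = []
    degenerate = 0
    for w in raw_maps:
        try:
            members.append(normalize_map(w))
        except DegenerateMapError:
            degenerate += 1
    if members:
        ensemble = MapEnsemble(tuple(members), provenance=dict(provenance))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            rep = interpretability(ensemble, reference)
            eta_true = (
                interpretability(ensemble, true_map).eta
                if true_map is not None
                else math.nan
            )
        eta_t, beta_t, psi = rep.eta, rep.beta, rep.psi
        zeta = scalarize(eta_t, delta, omega1, omega2, kappa)
    else:
        ensemble = None
        eta_t = beta_t = psi = eta_true = math.nan
        zeta = 0.0
    return LambdaEvaluation(
        lam=lam, delta=delta, epe=epe, bias=bias, variance=variance,
        psi=psi, beta_tilde=beta_t, eta_tilde=eta_t, zeta=zeta,
        ensemble=ensemble, degenerate_count=degenerate, eta_true=eta_true,
        full_map=full_map,
    )


def evaluate_lambda(
    data: EpochedDataset,
    lam: float,
    plan: PerturbationPlan,
    reference,
    *,
    omega1: float = 1.0,
    omega2: float = 1.0,
    kappa: float = 0.6,
    true_map=None,
    standardize: bool = True,
) -> LambdaEvaluation:
    """OOB evaluation of a single regularization strength.

    ``reference`` may be a CerfMap, an MBM, or a raw vector; ``true_map``
    optionally adds the exact interpretability against a known ground
    truth (simulations).
    """
    ref = _as_reference_map(reference)
    tmap = _as_reference_map(true_map) if true_map is not None else None
    raw_maps, preds = _run_grid(data, [lam], plan, standardize=standardize)
    lam = float(lam)
    prov = {"scheme": plan.scheme, "seed": plan.seed, "m": plan.m,
            "lambda": lam}
    return _evaluate_from_runs(
        lam, raw_maps[lam], preds[lam], data.labels, ref,
        omega1=omega1, omega2=omega2, kappa=kappa, true_map=tmap,
        provenance=prov, full_map=None,
    )


def select_model(
    data: EpochedDataset,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    *,
    m: int = 50,
    seed: int = 0,
    omega1: float = 1.0,
    omega2: float = 1.0,
    kappa: float = 0.6,
    reference=None,
    true_map=None,
    standardize: bool = True,
    fit_full: bool = True,
) -> ModelSelectionTable:
    """Grid search over lambda maximizing the zeta criterion.

    The reference map defaults to the cERF computed once on the full
    provided training set before the replicate loop.  Ties in zeta are
    broken toward larger lambda (the sparser model).  The table is
    bit-reproducible for a fixed seed.
    """
    grid = [float(l) for l in grid]
    if not grid:
        raise ValueError("lambda grid must be nonempty")
    if reference is None:
        reference = compute_cerf(data)
    ref = _as_reference_map(reference)
    tmap = _as_reference_map(true_map) if true_map is not None else None

    plan = oob_partitions(data.n, m, seed)
    raw_maps, preds = _run_grid(data, grid, plan, standardize=standardize)

    full_maps = {lam: None for lam in raw_maps}
    if fit_full:
        coef = None
        for lam in sorted(raw_maps, reverse=True):
            dec = fit_lasso(data, lam, standardize=standardize,
                            warm_start_coef=coef)
            coef = dec.std_weights
            try:
                full_maps[lam] = normalize_map(dec.raw_weights)
            except DegenerateMapError:
                full_maps[lam] = None

    rows = []
    for lam in sorted(set(grid)):
        prov = {"scheme": plan.scheme, "seed": plan.seed, "m": plan.m,
                "lambda": lam}
        rows.append(
            _evaluate_from_runs(
                lam, raw_maps[lam], preds[lam], data.labels, ref,
                omega1=omega1, omega2=omega2, kappa=kappa, true_map=tmap,
                provenance=prov, full_map=full_maps[lam],
            )
        )

    # argmax zeta, ties toward larger lambda; rows are sorted ascending
    best = max(rows, key=lambda r: (r.zeta, r.lam))
    advisory = max(rows, key=lambda r: (r.delta, r.lam)).lam
    admissible = best.zeta > 0.0
    config = {
        "grid": sorted(set(grid)), "m": m, "seed": int(seed),
        "omega1": omega1, "omega2": omega2, "kappa": kappa,
        "standardize": standardize, "reference": type(reference).__name__,
    }
    return ModelSelectionTable(
        rows=tuple(rows),
        chosen_lambda=best.lam if admissible else None,
        admissible=admissible,
        advisory_lambda=advisory,
        config=config,
    )
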