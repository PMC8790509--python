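"""Monte-Carlo equating-error statistics: Bias, SEE and RMSE.

For a parameter with true value ``lambda`` and estimates ``lambda_hat_r``
over R replications:

    Bias = mean_r(lambda_hat_r - lambda)                (systematic error)
    SEE  = sqrt(mean_r((lambda_hat_r - mean(lambda_hat))^2))  (random error)
    RMSE = sqrt(mean_r((lambda_hat_r - lambda)^2))      (total error)

All use divisor R, so RMSE^2 = Bias^2 + SEE^2 holds exactly per parameter.
Condition tables aggregate per-parameter statistics across the items in
scope by an unweighted (signed, for Bias) mean — one number per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import DichotomousItemParams, ItemParams
from .simulate import FormPair, SimulationCondition


def _check(estimates) -> np.ndarray:
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one replication")
    return est


def bias(estimates: Sequence[float], truth: float) -> float:
    """Mean signed deviation of the estimates from the true value."""
    est = _check(estimates)
    return float(np.mean(est - truth))


def see(estimates: Sequence[float]) -> float:
    """Root mean squared deviation of the estimates from their replication mean."""
    est = _check(estimates)
    return float(np.sqrt(np.mean((est - est.mean()) ** 2)))


def rmse(estimates: Sequence[float], truth: float) -> float:
    """Root mean squared deviation of the estimates from the true value."""
    est = _check(estimates)
    return float(np.sqrt(np.mean((est - truth) ** 2)))


# ---------------------------------------------------------------------------
# Replication containers and condition summaries
# ---------------------------------------------------------------------------

@dataclass
class ReplicationEstimates:
    """Aligned truth/estimate pairs from the replications of one condition.

    ``item_truth`` maps item_id -> true ItemParams; ``item_estimates`` holds
    one dict per replication mapping item_id -> estimated ItemParams (items
    excluded from a fit may be absent).  Ability pairs are per replication
    arrays over the in-scope examinees.
    """

    condition: SimulationCondition
    fit_family: str
    item_truth: dict[str, ItemParams]
    item_estimates: list[dict[str, ItemParams]] = field(default_factory=list)
    ability_truth: list[np.ndarray] = field(default_factory=list)
    ability_estimates: list[np.ndarray] = field(default_factory=list)
    item_scope: tuple[str, ...] = ()
    n_failed: int = 0

    @property
    def n_replications(self) -> int:
        return len(self.item_estimates)


@dataclass(frozen=True)
class ErrorSummary:
    """One cell of a condition table: a parameter family's Bias/SEE/RMSE."""

    condition: SimulationCondition
    fit_family: str
    parameter: str  # 'a', 'b', 'b1'..'b4', 'theta'
    bias: float
    see: float
    rmse: float
    n_parameters: int
    scope: str


def default_item_scope(pair: FormPair, include_anchor_testlets: bool = False) -> tuple[str, ...]:
    """New-form testlet items: the item scope the condition tables report.

    By default only the new form's non-anchor testlet items are included;
    anchor testlets (shared with the base form) can be added via
    ``include_anchor_testlets``.
    """
    out = []
    for it in pair.new_items:
        if it.testlet_id is None:
            continue
        if it.item_id in pair.anchor_ids and not include_anchor_testlets:
            continue
        out.append(it.item_id)
    return tuple(out)


def _param_values(item: ItemParams) -> dict[str, float]:
    if isinstance(item, DichotomousItemParams):
        return {"a": item.a, "b": item.b}
    vals = {"a": item.a}
    vals.update({f"b{k + 1}": v for k, v in enumerate(item.boundaries)})
    return vals


def summarize_condition(
    reps: ReplicationEstimates,
    scope: Iterable[str] | None = None,
) -> list[ErrorSummary]:
    """Per-parameter-family error statistics for one condition.

    Item statistics are computed per item over replications and then averaged
    (unweighted, signed for Bias) across the in-scope items.  Ability
    statistics pool the examinees within each replication and average the
    per-replication values across replications.
    """
    if reps.n_replications < 1:
        raise ValueError("no replications to summarize")
    scope_ids = tuple(scope) if scope is not None else reps.item_scope
    scope_label = "custom" if scope is not None else "new_form_testlet_items"

    families: dict[str, dict[str, tuple[list[float], float]]] = {}
    for iid in scope_ids:
        truth = reps.item_truth[iid]
        tvals = _param_values(truth)
        for rep_est in reps.item_estimates:
            est = rep_est.get(iid)
            if est is None:
                continue
            evals = _param_values(est)
            for name, tv in tvals.items():
                fam = families.setdefault(name, {})
                series, _ = fam.setdefault(iid, ([], tv))
                series.append(evals[name])

    out: list[ErrorSummary] = []
    for name in sorted(families):
        per_item = families[name]
        biases, sees, rmses = [], [], []
        for iid, (series, tv) in per_item.items():
            if not series:
                continue
            biases.append(bias(series, tv))
            sees.append(see(series))
            rmses.append(rmse(series, tv))
        if biases:
            out.append(
                ErrorSummary(
                    condition=reps.condition,
                    fit_family=reps.fit_family,
                    parameter=name,
                    bias=float(np.mean(biases)),
                    see=float(np.mean(sees)),
                    rmse=float(np.mean(rmses)),
                    n_parameters=len(biases),
                    scope=scope_label,
                )
            )

    if reps.ability_truth:
        rb, rs, rr = [], [], []
        for truth_vec, est_vec in zip(reps.ability_truth, reps.ability_estimates):
            err = np.asarray(est_vec) - np.asarray(truth_vec)
            b = float(err.mean())
            r2 = float(np.mean(err**2))
            rb.append(b)
            rr.append(np.sqrt(r2))
            rs.append(np.sqrt(max(r2 - b**2, 0.0)))
        out.append(
            ErrorSummary(
                condition=reps.condition,
                fit_family=reps.fit_family,
                parameter="theta",
                bias=float(np.mean(rb)),
                see=float(np.mean(rs)),
                rmse=float(np.mean(rr)),
                n_parameters=len(reps.ability_truth[0]),
                scope="new_form_examinees",
            )
        )
    return out


def summaries_to_frame(summaries: Iterable[ErrorSummary]) -> pd.DataFrame:
    """Flatten summaries into a tidy table keyed by the design factors."""
    rows = []
    for s in summaries:
        c = s.condition
        rows.append(
            {
                "data_family": c.data_family,
                "fit_family": s.fit_family,
                "sample_size": c.sample_size,
                "testlet_length": c.testlet_length,
                "testlet_effect": c.testlet_effect,
                "parameter": s.parameter,
                "bias": s.bias,
                "see": s.see,
                "rmse": s.rmse,
                "n_parameters": s.n_parameters,
                "scope": s.scope,
            }
        )
    return pd.DataFrame(rows)
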