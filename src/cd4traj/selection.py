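"""AIC model selection over candidate fixed-effect structures.

Each of the three curve parameters can carry one of four designs, giving
4^3 = 64 candidate structures.  Every candidate is fit to the same cohort;
candidates are ranked by AIC among converged fits, and the winner is
"clearly distinguishable" when every other converged candidate sits more
than 2 AIC units above it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import CD4TrajectoryModel
from .structures import ModelStructure, enumerate_structures

__all__ = ["fit_structures", "select_best", "reduced_grid", "enumerate_structures"]


def reduced_grid() -> list[ModelStructure]:
    """Eight-candidate grid for fast sweeps: intercept and asymptote share
    a common design, rate is constant or age-dependent.  Contains the
    best-supported structure."""
    out = []
    for d in ("constant", "sex", "age", "age_sex"):
        for r in ("constant", "age"):
            out.append(ModelStructure(d, d, r))
    return out


def fit_structures(cohort, structures=None, fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Fit every candidate structure and tabulate the AIC comparison.

    Returns one row per candidate: structure label, parameter count,
    log-likelihood, AIC, convergence flag, delta-AIC from the best
    converged fit, and rank (non-converged fits keep their diagnostics but
    are excluded from ranking).  Models share per-patient starting values
    only implicitly (each model recomputes them); rows appear in candidate
    order, so the table is reproducible.
    """
    if structures is None:
        structures = enumerate_structures()
    fit_kwargs = fit_kwargs or {}
    rows = []
    for s in structures:
        s = ModelStructure(*s).validate()
        res = CD4TrajectoryModel(cohort, structure=s).fit(**fit_kwargs)
        rows.append(
            {
                "structure": s.label(),
                "n_params": res.k_params,
                "loglik": res.llf,
                "aic": res.aic,
                "converged": res.converged,
            }
        )
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    if len(conv):
        best = conv["aic"].min()
        table["delta_aic"] = np.where(table["converged"], table["aic"] - best, np.nan)
        order = conv.sort_values(["aic", "n_params"], kind="mergesort").index
        table["rank"] = np.nan
        table.loc[order, "rank"] = np.arange(1, len(order) + 1)
    else:
        table["delta_aic"] = np.nan
        table["rank"] = np.nan
    return table


def select_best(table: pd.DataFrame) -> tuple[ModelStructure, bool]:
    """Minimum-AIC converged structure and its distinguishability flag.

    The flag is True iff every other converged candidate is more than
    2 AIC units worse.  AIC ties break toward fewer parameters, then
    earlier candidate order.  Raises if no candidate converged.
    """
    conv = table[table["converged"]]
    if conv.empty:
        raise ValueError("no converged candidate fits to select from")
    conv = conv.sort_values(["aic", "n_params"], kind="mergesort")
    best = conv.iloc[0]
    others = conv.iloc[1:]
    distinguishable = bool((others["aic"] - best["aic"] > 2.0).all())
    return ModelStructure.from_label(best["structure"]), distinguishable
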