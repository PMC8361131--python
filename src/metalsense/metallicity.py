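"""The two-parameter metallicity model.

Metallicity is modeled as a weighted combination of two steerable-pyramid
level activations: ``m = a * A_4 + b * A_1``, where A_1 responds to fine
image detail and A_4 to coarse structure.  The two weights are the model's
only free parameters; fitting them to an observer's conjoint-measurement
scale captures individual differences (including sign inversions — an
observer who equates roughness with metallicity simply has negative
weights).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import ConjointFit, fit_mlcm
from .pyramid import build_pyramid, level_activations
from .trials import ModelObserver, PairTrial, simulate_responses

__all__ = [
    "MetallicityWeights",
    "metallicity_statistic",
    "activation_table_from_images",
    "fit_weights_to_scale",
    "simulate_model_conjoint",
    "reproduce_deposited_weights",
]


@dataclass
class MetallicityWeights:
    """Weights of the two-level metallicity model: ``a`` on Level 4
    (coarse features), ``b`` on Level 1 (fine details)."""

    a: float
    b: float
    loss: float = 0.0
    fit_method: str = "closed_form"


def metallicity_statistic(img, weights: MetallicityWeights) -> float:
    """m = a * A_4 + b * A_1.  Weights (0, 1) reduce to the smoothness
    statistic A_1; (-1, 1) to the bumpiness statistic A_1 - A_4."""
    A = level_activations(build_pyramid(img)).A
    return float(weights.a * A[3] + weights.b * A[0])


def activation_table_from_images(images) -> pd.DataFrame:
    """Per-(condition, view) pyramid activations A_1..A_4 of a stimulus
    set."""
    rows = []
    for img in images:
        A = level_activations(build_pyramid(img)).A
        rows.append(dict(
            smoothness_index=img.smoothness_index,
            bumpiness_index=img.bumpiness_index,
            view_index=img.view_index,
            **{f"A{i+1}": A[i] for i in range(len(A))},
        ))
    return pd.DataFrame(rows)


def _view_averaged(activations: pd.DataFrame) -> pd.DataFrame:
    return (
        activations.groupby(["smoothness_index", "bumpiness_index"])[["A1", "A4"]]
        .mean()
        .reset_index()
    )


def fit_weights_to_scale(
    observer_fit: ConjointFit, activation_table: pd.DataFrame
) -> MetallicityWeights:
    """Closed-form least-squares fit of the model weights to an observer's
    conjoint scale.

    The observer's additive cell values psi_S(i) + psi_B(j) are regressed
    on the view-averaged activations (A_4, A_1) per grid cell, with a free
    intercept absorbing the anchoring convention.  Deterministic.
    """
    avg = _view_averaged(activation_table)
    cells = observer_fit.cell_values()
    y = np.array([
        cells[int(r.smoothness_index), int(r.bumpiness_index)]
        for r in avg.itertuples()
    ])
    X = np.column_stack([avg["A4"].to_numpy(), avg["A1"].to_numpy(),
                         np.ones(len(avg))])
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError(
            "activation predictors are rank-deficient (A1 and A4 collinear "
            "or constant over the grid)"
        )
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    loss = float(res[0]) if res.size else float(np.sum((X @ coef - y) ** 2))
    return MetallicityWeights(a=float(coef[0]), b=float(coef[1]), loss=loss)


def simulate_model_conjoint(
    weights: MetallicityWeights,
    session: Sequence[PairTrial],
    activation_table: pd.DataFrame,
    noise_sd: float = 1.0,
    seed: int = 0,
    model_class: str = "additive",
) -> ConjointFit:
    """Run the weighted model as a noisy observer through a conjoint
    session and fit its scale — the model's predicted conjoint
    contributions, comparable to (and overlayable on) observer fits.
    Weights (0, 1) and (0, -1) give the pure-Level-1 model and its sign
    inversion."""
    table = {
        (int(r.smoothness_index), int(r.bumpiness_index), int(r.view_index)):
            weights.a * r.A4 + weights.b * r.A1
        for r in activation_table.itertuples()
    }
    observer = ModelObserver(statistic="metallicity", noise_sd=noise_sd, seed=seed)
    responded = simulate_responses(session, observer, table)
    return fit_mlcm(responded, model_class)


def reproduce_deposited_weights(
    deposited_dir, activation_table: pd.DataFrame | None = None
) -> pd.DataFrame | None:
    """Optional reproduction path against deposited observer data.

    Expects a directory with per-observer conjoint-scale CSVs (columns:
    observer, smoothness_index, bumpiness_index, psi).  Returns a
    per-observer table of fitted (L1, L4) weights for side-by-side,
    qualitative comparison — no numeric agreement is asserted, since
    synthetic activations differ from those of the original rendered
    stimuli.  Returns None (with a message) when the data are absent.
    """
    deposited_dir = Path(deposited_dir)
    scales_path = deposited_dir / "observer_scales.csv"
    if not scales_path.exists():
        print(f"optional deposited data not present under {deposited_dir}; skipping")
        return None
    df = pd.read_csv(scales_path)
    required = {"observer", "smoothness_index", "bumpiness_index", "psi"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"deposited scale table missing columns: {sorted(missing)}")
    if activation_table is None:
        raise ValueError("activation_table required when deposited data present")
    avg = _view_averaged(activation_table)
    rows = []
    for obs, g in df.groupby("observer"):
        merged = avg.merge(g, on=["smoothness_index", "bumpiness_index"])
        X = np.column_stack([merged["A4"], merged["A1"], np.ones(len(merged))])
        coef, *_ = np.linalg.lstsq(X, merged["psi"].to_numpy(), rcond=None)
        rows.append(dict(observer=obs, L4=coef[0], L1=coef[1]))
    return pd.DataFrame(rows)
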