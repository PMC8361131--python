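"""End-to-end orchestration: stimuli -> statistics -> simulated sessions ->
fits -> reports and figures.

Every run is a pure function of its :class:`~metalsense.config.RunConfig`
(including the seed); the config hash is recorded in every output file so
artifacts can be traced to the exact configuration that produced them.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrast as C
from . import pyramid as P
from . import spectral as SP
from .config import RunConfig, substream_seed
from .fitting import SeparationWarning, fit_mlcm, fit_mlds, lr_test
from .metallicity import activation_table_from_images, fit_weights_to_scale
from .stimuli import render_grid, render_mlds_set
from .trials import (
    ModelObserver,
    build_mlcm_session,
    build_mlds_session,
    default_noise_sd,
    enumerate_mlcm_pairs,
    enumerate_mlds_quadruples,
    simulate_responses,
)

__all__ = ["run_all", "report", "statistic_tables"]


def statistic_tables(images, statistics=None) -> pd.DataFrame:
    """One row per (condition, view) with pyramid activations and the nine
    contrast estimators."""
    rows = []
    for img in images:
        A = P.level_activations(P.build_pyramid(img)).A
        row = dict(
            smoothness_index=img.smoothness_index,
            bumpiness_index=img.bumpiness_index,
            view_index=img.view_index,
            **{f"A{i+1}": A[i] for i in range(len(A))},
            A1_minus_A4=A[0] - A[-1],
        )
        sample = C.extract_sample(img, with_blur=True)
        for name, fn in C.CONTRAST_STATISTICS.items():
            if statistics is not None and name not in statistics:
                continue
            try:
                row[name] = fn(sample)
            except C.DegenerateStatisticError:
                row[name] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _stat_lookup(stats_df: pd.DataFrame, statistic: str) -> dict:
    if statistic not in stats_df.columns:
        raise KeyError(f"unknown statistic {statistic!r}")
    return {
        (int(r.smoothness_index), int(r.bumpiness_index), int(r.view_index)):
            getattr(r, statistic)
        for r in stats_df.itertuples()
    }


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns a dict of result objects and writes
    CSV/JSON (and figures, if enabled) under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    results: dict = {"config_hash": chash}
    stage = "generate"
    try:
        scfg = config.stimulus
        grid_images = render_grid(scfg)
        stage = "statistics"
        stats_df = statistic_tables(grid_images)
        stats_df.insert(0, "config_hash", chash)
        stats_df.to_csv(out / "grid_statistics.csv", index=False)
        results["statistics"] = stats_df

        if config.compute_spectra:
            stage = "spectra"
            spec_rows = []
            for img in grid_images:
                sp = SP.radial_power_spectrum(img)
                spec_rows.append(dict(
                    config_hash=chash,
                    smoothness_index=img.smoothness_index,
                    bumpiness_index=img.bumpiness_index,
                    view_index=img.view_index,
                    band_mean_23_53=SP.band_mean_power(sp),
                    loglog_slope=SP.loglog_slope(
                        sp, (4, scfg.image_size // 4)),
                ))
            spectra_df = pd.DataFrame(spec_rows)
            spectra_df.to_csv(out / "grid_spectra.csv", index=False)
            results["spectra"] = spectra_df

        stage = "mlds"
        mlds_images = render_mlds_set(scfg, config.mlds_n_levels)
        mlds_results = {}
        for dim, key in (("smoothness", "A1"), ("bumpiness", "A1_minus_A4")):
            dim_stats = statistic_tables(mlds_images[dim], statistics=())
            table = {
                (int(r.smoothness_index) if dim == "smoothness"
                 else int(r.bumpiness_index), int(r.view_index)): getattr(r, key)
                for r in dim_stats.itertuples()
            }
            quads = enumerate_mlds_quadruples(config.mlds_n_levels)
            session = build_mlds_session(
                quads, dim, scfg.n_views,
                seed=substream_seed(config.seed, "session", 0),
            )
            obs = ModelObserver(
                statistic=key,
                noise_sd=default_noise_sd(table),
                seed=substream_seed(config.seed, "noise", 0),
            )
            responded = simulate_responses(session, obs, table)
            mlds_results[dim] = fit_mlds(responded)
        results["mlds"] = mlds_results

        stage = "mlcm"
        pairs = enumerate_mlcm_pairs(scfg.n_smoothness_levels, scfg.n_bumpiness_levels)
        observer_rows = []
        conjoint_fits = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SeparationWarning)
            for i, (stat_name, noise_sd) in enumerate(config.observers):
                table = _stat_lookup(stats_df, stat_name)
                if any(not np.isfinite(v) for v in table.values()):
                    raise ValueError(f"statistic {stat_name} undefined on some images")
                if noise_sd == 0:
                    noise_sd = default_noise_sd(table)
                session = build_mlcm_session(
                    pairs, config.n_mlcm_repeats, scfg.n_views,
                    seed=substream_seed(config.seed, "session", i + 1),
                )
                responded = simulate_responses(
                    session,
                    ModelObserver(stat_name, noise_sd,
                                  substream_seed(config.seed, "noise", i + 1)),
                    table,
                )
                ind = fit_mlcm(responded, "independent")
                add = fit_mlcm(responded, "additive")
                sat = fit_mlcm(responded, "saturated")
                lr_ia = lr_test(ind, add)
                lr_as = lr_test(add, sat)
                if lr_ia.p_value >= config.alpha:
                    selected = "independent"
                elif lr_as.p_value < config.alpha:
                    selected = "saturated"
                else:
                    selected = "additive"
                conjoint_fits[stat_name] = add
                observer_rows.append(dict(
                    config_hash=chash, statistic=stat_name, noise_sd=noise_sd,
                    ll_independent=ind.log_likelihood,
                    ll_additive=add.log_likelihood,
                    ll_saturated=sat.log_likelihood,
                    p_ind_vs_add=lr_ia.p_value, p_add_vs_sat=lr_as.p_value,
                    selected_model=selected,
                    psi_s=json.dumps(list(np.round(add.psi_s, 4))),
                    psi_b=json.dumps(list(np.round(add.psi_b, 4))),
                ))
        observers_df = pd.DataFrame(observer_rows)
        observers_df.to_csv(out / "observer_models.csv", index=False)
        results["observers"] = observers_df
        results["conjoint_fits"] = conjoint_fits

        stage = "metallicity"
        act = activation_table_from_images(grid_images)
        weight_rows = []
        for stat_name, fit in conjoint_fits.items():
            w = fit_weights_to_scale(fit, act)
            weight_rows.append(dict(config_hash=chash, observer=stat_name,
                                    L1=w.b, L4=w.a, loss=w.loss))
        weights_df = pd.DataFrame(weight_rows)
        weights_df.to_csv(out / "metallicity_weights.csv", index=False)
        results["weights"] = weights_df

        with open(out / "run_summary.json", "w") as fh:
            json.dump(dict(
                config_hash=chash,
                config=config.to_dict(),
                mlds={d: list(np.round(f.psi, 4)) for d, f in mlds_results.items()},
                n_grid_images=len(grid_images),
                n_mlds_images=sum(len(v) for v in mlds_images.values()),
            ), fh, indent=2)

        if config.make_figures:
            stage = "figures"
            _make_figures(out, results, config)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (config {chash}): {exc}"
        ) from exc
    return results


def _make_figures(out: Path, results: dict, config: RunConfig) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # Activation heatmaps (per-level mean activation over the grid).
    stats_df = results["statistics"]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    for lvl, ax in enumerate(axes, start=1):
        piv = stats_df.pivot_table(index="smoothness_index",
                                   columns="bumpiness_index", values=f"A{lvl}")
        im = ax.imshow(piv.to_numpy(), origin="lower", cmap="viridis")
        ax.set_title(f"Level {lvl} activation")
        ax.set_xlabel("bumpiness level")
        ax.set_ylabel("smoothness level")
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out / "activation_heatmaps.png", dpi=120)
    plt.close(fig)

    # Difference scales.
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    for ax, (dim, scale) in zip(axes, results["mlds"].items()):
        ax.plot(scale.psi, "o-")
        ax.set_title(f"simulated difference scale: {dim}")
        ax.set_xlabel("stimulus level")
        ax.set_ylabel("scale value (d')")
    fig.tight_layout()
    fig.savefig(out / "difference_scales.png", dpi=120)
    plt.close(fig)

    # Conjoint contributions per observer.
    fits = results["conjoint_fits"]
    if fits:
        n = len(fits)
        fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.2), sharey=True,
                                 squeeze=False)
        for ax, (name, f) in zip(axes[0], fits.items()):
            ax.plot(f.psi_s, "o-", color="seagreen", label="smoothness")
            ax.plot(f.psi_b, "s-", color="steelblue", label="bumpiness")
            ax.axhline(0, color="0.7", lw=0.8)
            ax.set_title(name)
            ax.set_xlabel("level")
        axes[0][0].set_ylabel("contribution (d')")
        axes[0][0].legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "conjoint_contributions.png", dpi=120)
        plt.close(fig)


def report(run_dir) -> pd.DataFrame:
    """Tabulate, per simulated observer, the conjoint model class selected
    by nested LR tests — the analogue of a 'resultant model' column."""
    run_dir = Path(run_dir)
    path = run_dir / "observer_models.csv"
    if not path.exists():
        raise FileNotFoundError(f"no observer_models.csv under {run_dir}")
    df = pd.read_csv(path)
    cols = ["statistic", "selected_model", "p_ind_vs_add", "p_add_vs_sat",
            "psi_s", "psi_b"]
    return df[cols]
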