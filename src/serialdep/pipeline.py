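"""End-to-end orchestration: simulate → preprocess → analyse → report.

``run_full_study`` mirrors the structure of a complete study of serial
dependence under stimulus-uncertainty manipulation: a simulated cohort
of adjustment sessions, preprocessing with exclusion rules, DoG fits
with sign-flip permutation tests per noise transition (stimulus- and
response-contingent), the pairwise condition-difference permutation
matrix, the model-free bias statistic with its 2×2 repeated-measures
ANOVA, the two control analyses (t+1 and alternate-flip), and the
binary-task probit analysis.  Every stochastic stage draws its seed
from the master seed, so a run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binary import compare_spreads, fit_all_probit
from .model_free import bias_table, rm_anova_2x2
from .oblique import fit_all, fits_to_frame, residualize
from .observers import ObserverParams, simulate_binary_experiment, simulate_experiment
from .preprocess import exclude_participants, preprocess
from .serial import (
    alternate_flip,
    condition_on_previous,
    permutation_test_amplitude,
    permutation_test_difference,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_study"]

TRANSITIONS = ("LL", "HH", "LH", "HL")
MODES = ("stimulus_contingent", "response_contingent")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full study run byte for byte."""

    seed: int = 1
    # cohort
    n_participants: int = 20
    n_trials: int = 821
    # generative observer
    amplitude_ll: float = 1.7
    amplitude_hl: float = 1.7
    amplitude_lh: float = 3.0
    amplitude_hh: float = 3.0
    dog_width: float = 0.05
    sigma_low_deg: float = 4.0
    sigma_high_deg: float = 8.0
    global_bias_deg: float = 1.0
    oblique_amp_low_deg: float = 6.0
    oblique_amp_high_deg: float = 8.0
    lapse_rate: float = 0.01
    conditioning: str = "previous_response"
    # binary task
    n_binary_participants: int = 16
    binary_spread_low_deg: float = 4.23
    binary_spread_high_deg: float = 25.24
    binary_between_cv: float = 0.2
    n_binary_trials: int = 200
    # analysis
    n_perm: int = 10000
    window_deg: int = 20
    n_harmonics: int = 2
    make_plots: bool = False

    def observer_params(self) -> ObserverParams:
        return ObserverParams(
            dog_amplitude_deg={
                "LL": self.amplitude_ll,
                "HL": self.amplitude_hl,
                "LH": self.amplitude_lh,
                "HH": self.amplitude_hh,
            },
            dog_width=self.dog_width,
            sigma_low_deg=self.sigma_low_deg,
            sigma_high_deg=self.sigma_high_deg,
            global_bias_deg=self.global_bias_deg,
            oblique_coeffs={
                "low": np.array([[0.0, 0.0], [self.oblique_amp_low_deg, 0.0]]),
                "high": np.array([[0.0, 0.0], [self.oblique_amp_high_deg, 0.0]]),
            },
            lapse_rate=self.lapse_rate,
            conditioning=self.conditioning,  # type: ignore[arg-type]
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit child seeds for the run's stochastic stages."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _amplitude_suite(table, mode, n_perm, window_deg, seed):
    """Pooled + per-transition sign-flip amplitude tests for one mode."""
    series = condition_on_previous(table, mode)
    rows = []
    results = {}
    for i, trans in enumerate(("pooled",) + TRANSITIONS):
        sub = series.for_transition(trans)
        res = permutation_test_amplitude(
            sub, n_perm=n_perm, seed=seed + i, window_deg=window_deg
        )
        fit = res.observed_fit
        rows.append(
            {
                "mode": mode,
                "transition": trans,
                "a_deg": res.observed_stat,
                "w": fit.w,
                "b_deg": fit.b,
                "rmse_deg": fit.rmse,
                "w_at_bound": fit.w_at_bound,
                "p": res.p,
                "p_display": res.p_display,
                "n_perm": res.n_perm,
            }
        )
        results[trans] = res
    return pd.DataFrame(rows), results, series


def _difference_matrix(series, mode, n_perm, window_deg, seed):
    rows = []
    pairs = [(a, b) for i, a in enumerate(TRANSITIONS) for b in TRANSITIONS[i + 1:]]
    for j, (ca, cb) in enumerate(pairs):
        res = permutation_test_difference(
            series.for_transition(ca),
            series.for_transition(cb),
            n_perm=n_perm,
            seed=seed + j,
            window_deg=window_deg,
        )
        rows.append(
            {
                "mode": mode,
                "condition_a": ca,
                "condition_b": cb,
                "diff_deg": res.observed_stat,
                "p": res.p,
                "p_display": res.p_display,
                "n_perm": res.n_perm,
            }
        )
    return pd.DataFrame(rows)


def run_full_study(config: RunConfig, out_dir) -> dict:
    """Run the whole pipeline and write all outputs under ``out_dir``.

    Returns a dict of in-memory results (DataFrames and summary dicts);
    a manifest recording the config, its hash, the package version and
    all derived seeds is written alongside the CSVs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (seed_sim, seed_binary, seed_perm_s, seed_perm_r, seed_diff,
     seed_ctrl, seed_cmp) = _spawn_seeds(config.seed, 7)

    # --- simulate ---------------------------------------------------------
    params = config.observer_params()
    trials = simulate_experiment(
        params, config.n_participants, config.n_trials, seed=seed_sim
    )
    trials.to_csv(out / "trials.csv", index=False)

    # --- preprocess -------------------------------------------------------
    clean, reports = preprocess(trials)
    clean.to_csv(out / "trials_preprocessed.csv", index=False)
    for name, rep in reports.items():
        rep.to_csv(out / f"report_{name}.csv")
    removed_pct = float(reports["outliers"].table["fraction_removed"].mean() * 100)

    # --- oblique correction (response-contingent route only) -------------
    fits = fit_all(clean, config.n_harmonics)
    fits_to_frame(fits).to_csv(out / "oblique_fits.csv", index=False)
    corrected = residualize(clean, fits)

    # --- DoG + permutation tests -----------------------------------------
    dog_s, res_s, series_s = _amplitude_suite(
        clean, "stimulus_contingent", config.n_perm, config.window_deg, seed_perm_s
    )
    dog_r, res_r, series_r = _amplitude_suite(
        corrected, "response_contingent", config.n_perm, config.window_deg, seed_perm_r
    )
    dog_fits = pd.concat([dog_s, dog_r], ignore_index=True)
    dog_fits.to_csv(out / "dog_fits.csv", index=False)

    differences = pd.concat(
        [
            _difference_matrix(series_s, "stimulus_contingent", config.n_perm,
                               config.window_deg, seed_diff),
            _difference_matrix(series_r, "response_contingent", config.n_perm,
                               config.window_deg, seed_diff + 100),
        ],
        ignore_index=True,
    )
    differences.to_csv(out / "differences.csv", index=False)

    # --- model-free -------------------------------------------------------
    anova_rows, bias_frames = [], []
    for mode, tbl in (("stimulus_contingent", clean), ("response_contingent", corrected)):
        series = condition_on_previous(tbl, mode)
        bias = bias_table(series)
        bias["mode"] = mode
        bias_frames.append(bias)
        a = rm_anova_2x2(bias)
        af = a.to_frame()
        af["mode"] = mode
        anova_rows.append(af)
    bias_all = pd.concat(bias_frames, ignore_index=True)
    anova_all = pd.concat(anova_rows, ignore_index=True)
    bias_all.to_csv(out / "model_free_bias.csv", index=False)
    anova_all.to_csv(out / "model_free_anova.csv", index=False)

    # --- controls ---------------------------------------------------------
    ctrl_rows = []
    tplus = condition_on_previous(clean, "stimulus_contingent", offset=+1)
    for i, trans in enumerate(("pooled",) + TRANSITIONS):
        res = permutation_test_amplitude(
            tplus.for_transition(trans), n_perm=config.n_perm,
            seed=seed_ctrl + i, window_deg=config.window_deg,
        )
        ctrl_rows.append({"control": "t_plus_1", "mode": "stimulus_contingent",
                          "transition": trans, "a_deg": res.observed_stat,
                          "p": res.p, "p_display": res.p_display})
    flipped = alternate_flip(clean)
    flipped_corrected = residualize(flipped, fit_all(flipped, config.n_harmonics))
    for label, tbl in (("uncorrected", flipped), ("corrected", flipped_corrected)):
        res = permutation_test_amplitude(
            condition_on_previous(tbl, "response_contingent"),
            n_perm=config.n_perm, seed=seed_ctrl + 50, window_deg=config.window_deg,
        )
        ctrl_rows.append({"control": f"alternate_flip_{label}",
                          "mode": "response_contingent", "transition": "pooled",
                          "a_deg": res.observed_stat, "p": res.p,
                          "p_display": res.p_display})
    controls = pd.DataFrame(ctrl_rows)
    controls.to_csv(out / "controls.csv", index=False)

    # --- binary task ------------------------------------------------------
    binary = simulate_binary_experiment(
        config.n_binary_participants,
        config.binary_spread_low_deg,
        config.binary_spread_high_deg,
        config.binary_between_cv,
        config.n_binary_trials,
        seed=seed_binary,
    )
    binary.to_csv(out / "binary_trials.csv", index=False)
    pfits = fit_all_probit(binary)
    pfits.to_csv(out / "binary_fits.csv", index=False)
    excl = exclude_participants(
        binary_spreads=pfits.rename(columns={"spread_deg": "spread_deg"})[
            ["participant_id", "spread_deg"]
        ]
    )
    kept = set(excl.table.loc[~excl.table["excluded"], "participant_id"])
    wide = pfits[pfits["participant_id"].isin(kept)].pivot(
        index="participant_id", columns="noise_level", values="spread_deg"
    )
    spread_cmp = compare_spreads(
        wide["low"].to_numpy(), wide["high"].to_numpy(),
        n_perm=config.n_perm, seed=seed_cmp,
    )
    spread_cmp["mean_spread_low_deg"] = float(wide["low"].mean())
    spread_cmp["mean_spread_high_deg"] = float(wide["high"].mean())
    (out / "binary_comparison.json").write_text(json.dumps(spread_cmp, indent=2))

    # --- adjustment-task accuracy summary ---------------------------------
    acc = (
        clean.assign(abs_error=clean["error_deg"].abs())
        .groupby("noise_level")["abs_error"]
        .mean()
    )

    # --- figures ----------------------------------------------------------
    if config.make_plots:
        from .plotting import plot_bias_summary, plot_transition_curves

        plot_transition_curves(series_s, series_r, config.window_deg,
                               out / "fig_transition_curves.png")
        plot_bias_summary(bias_all, out / "fig_model_free_bias.png")

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seeds": {
            "simulation": seed_sim,
            "binary": seed_binary,
            "perm_stimulus": seed_perm_s,
            "perm_response": seed_perm_r,
            "perm_difference": seed_diff,
            "controls": seed_ctrl,
            "spread_comparison": seed_cmp,
        },
        "n_trials_removed_pct": removed_pct,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return {
        "trials": trials,
        "clean": clean,
        "dog_fits": dog_fits,
        "differences": differences,
        "bias": bias_all,
        "anova": anova_all,
        "controls": controls,
        "binary_fits": pfits,
        "spread_comparison": spread_cmp,
        "removed_pct": removed_pct,
        "mean_abs_error": {k: float(v) for k, v in acc.items()},
        "amplitude_results": {"stimulus_contingent": res_s, "response_contingent": res_r},
        "manifest": manifest,
    }
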