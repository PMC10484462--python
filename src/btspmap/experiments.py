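"""Reproducible experiment driver.

Each experiment is a seeded, desk-scale end-to-end run of one figure-class
analysis (kernel/biophysics comparison, recurrent learning, theory-vs-
simulation, SNR capacity, ring bifurcation, network capacity, mixed
attractors).  A run validates its parameters against the experiment's
schema, funnels all randomness through sub-streams of a single seed,
writes CSV/HDF5 results plus a JSON manifest, and removes partial output
on failure.
"""

from __future__ import annotations

import json
import logging
import shutil
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import networks as nets
from . import plasticity as pl
from . import theory
from .io import save_learned_system
from .plasticity import MapParams
from .presets import reference_biophys_params, reference_map_params, reference_protocol

__all__ = [
    "ExperimentConfig",
    "ExperimentError",
    "load_config",
    "run_experiment",
    "summarize",
    "preset_configs",
]

log = logging.getLogger("btspmap")


class ExperimentError(RuntimeError):
    pass


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int
    output_dir: Path
    parameters: dict = field(default_factory=dict)


def load_config(path) -> ExperimentConfig:
    """Parse a TOML experiment config (keys: experiment, seed, output_dir,
    [parameters] table)."""
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    missing = [k for k in ("experiment", "seed", "output_dir") if k not in raw]
    if missing:
        raise ExperimentError(f"config {path}: missing field(s) {missing}")
    return ExperimentConfig(
        experiment=str(raw["experiment"]),
        seed=int(raw["seed"]),
        output_dir=Path(raw["output_dir"]),
        parameters=dict(raw.get("parameters", {})),
    )


def _validate(params: dict, schema: dict, experiment: str) -> dict:
    unknown = sorted(set(params) - set(schema))
    if unknown:
        raise ExperimentError(
            f"{experiment}: unknown parameter field(s): "
            + ", ".join(f"parameters.{k}" for k in unknown)
        )
    out = {k: default for k, default in schema.items()}
    out.update(params)
    return out


def _rngs(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# experiment implementations — each returns a JSON-serializable summary


def _learned_system(N, M, s, n, P, D, seed):
    """Learn one recurrent matrix from a uniform random initial state."""
    seq = pl.generate_environment_sequence(N, M, s, n, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    W0 = rng.random((seq.n_cells, seq.n_cells))
    W, _ = pl.recurrent_learn(W0, seq, MapParams.cosine(P, D))
    return W, seq


def _exp_kernel_fit_compare(params, seed, outdir):
    schema = {"velocity": 25.0, "dt": 0.01, "x_pp": 93.5}
    p = _validate(params, schema, "kernel_fit_compare")
    proto = reference_protocol(plateau_positions=(p["x_pp"],), dt=p["dt"])
    mp = reference_map_params(v=p["velocity"])
    table, r = pl.map_vs_biophys(proto, reference_biophys_params(), mp)
    table.to_csv(outdir / "comparison.csv", index=False)
    pd.concat(
        [
            mp.f_p.to_frame().assign(kernel="potentiation"),
            mp.f_d.to_frame().assign(kernel="depression"),
        ]
    ).to_csv(outdir / "kernels.csv", index=False)
    return {"pearson_r": r, "n_grid_points": len(table)}


def _exp_feedforward_protocol(params, seed, outdir):
    schema = {"plateau_positions": [30.0, 90.0], "dt": 0.01}
    p = _validate(params, schema, "feedforward_protocol")
    proto = reference_protocol(plateau_positions=tuple(p["plateau_positions"]), dt=p["dt"])
    bio_hist = None
    import btspmap.biophys as bp

    bio_hist = bp.run_protocol(proto, reference_biophys_params(), np.zeros(proto.n_inputs))
    mp = reference_map_params()
    theta = 2.0 * np.pi * proto.input_positions() / proto.track_length
    w = np.zeros(proto.n_inputs)
    map_hist = [w.copy()]
    for x_pp in proto.plateau_positions:
        w = pl.feedforward_induction(
            w, 2.0 * np.pi * x_pp / proto.track_length, mp, theta=theta
        )
        map_hist.append(w.copy())
    rows = []
    for lap in range(len(map_hist)):
        for i, pos in enumerate(proto.input_positions()):
            rows.append((lap, pos, map_hist[lap][i], bio_hist[lap][i]))
    pd.DataFrame(rows, columns=["lap", "position", "w_map", "w_biophys"]).to_csv(
        outdir / "profiles.csv", index=False
    )
    pk_map = float(proto.input_positions()[np.argmax(map_hist[-1])])
    pk_bio = float(proto.input_positions()[np.argmax(bio_hist[-1])])
    return {"final_peak_map_cm": pk_map, "final_peak_biophys_cm": pk_bio}


def _exp_recurrent_learning(params, seed, outdir):
    schema = {"N": 64, "M": 2, "s": 0.5, "n": 40, "P": 0.3, "D": 0.3}
    p = _validate(params, schema, "recurrent_learning")
    W, seq = _learned_system(p["N"], p["M"], p["s"], p["n"], p["P"], p["D"], seed)
    save_learned_system(outdir / "system.h5", W, seq, {"P": p["P"], "D": p["D"]})
    stats = pl.empirical_trace_stats(W, seq, eta=0)
    stats.to_frame().to_csv(outdir / "ordered_stats_eta0.csv", index=False)
    mu_t, var_t = theory.steady_state_moments(MapParams.cosine(p["P"], p["D"]))
    return {
        "mean_weight": stats.mean_weight,
        "mean_weight_theory": mu_t,
        "variance_theory": var_t,
        "amplitude_eta0": stats.amplitude,
    }


def _exp_trace_theory_vs_sim(params, seed, outdir):
    schema = {
        "N": 64, "M": 4, "s": 0.5, "n": 60, "P": 0.3, "D": 0.3,
        "replicates": 8, "eta_max": 5,
    }
    p = _validate(params, schema, "trace_theory_vs_sim")
    etas = np.arange(p["eta_max"] + 1)
    ts = theory.memory_trace(etas, p["P"], p["D"], p["s"])
    amps = np.empty((p["replicates"], etas.size))
    meanvar = np.empty_like(amps)
    for rep in range(p["replicates"]):
        W, seq = _learned_system(
            p["N"], p["M"], p["s"], p["n"], p["P"], p["D"], seed + 17 * (rep + 1)
        )
        for j, eta in enumerate(etas):
            st = pl.empirical_trace_stats(W, seq, int(eta))
            amps[rep, j] = st.amplitude
            meanvar[rep, j] = float(np.nanmean(st.var_profile))
    df = pd.DataFrame(
        {
            "P": p["P"], "D": p["D"], "s": p["s"], "M": p["M"], "eta": etas,
            "a_emp_mean": amps.mean(0), "a_emp_sd": amps.std(0, ddof=1),
            "a_theory": ts.a,
            "var_emp_mean": meanvar.mean(0), "var_emp_sd": meanvar.std(0, ddof=1),
            "var_theory": ts.mean_variance(),
        }
    )
    df["a_within_band"] = (
        np.abs(df.a_emp_mean - df.a_theory)
        <= 1.96 * df.a_emp_sd / np.sqrt(p["replicates"])
        + 0.02 * np.abs(df.a_theory)
    )
    df.to_csv(outdir / "curves.csv", index=False)
    return {
        "n_eta": int(etas.size),
        "n_within_band": int(df.a_within_band.sum()),
        "max_rel_amp_error": float(
            np.max(np.abs(df.a_emp_mean - df.a_theory) / np.abs(df.a_theory))
        ),
    }


def _exp_snr_capacity(params, seed, outdir):
    schema = {"P": 0.3, "T": 1.0, "s_list": [0.05, 0.1, 0.2], "M_list": [50, 100, 200]}
    p = _validate(params, schema, "snr_capacity")
    rows = []
    for s in p["s_list"]:
        for M in p["M_list"]:
            cap = theory.snr_capacity(s, M, p["P"], p["T"])
            rows.append(
                (s, M, cap.eta_max, cap.eta_max_real, cap.eta_max_closed,
                 cap.eta_max_asymptotic)
            )
    df = pd.DataFrame(
        rows, columns=["s", "M", "eta_max", "eta_max_real", "closed", "asymptotic"]
    )
    df.to_csv(outdir / "capacity.csv", index=False)
    return {"max_abs_gap_exact_vs_closed": float((df.eta_max_real - df.closed).abs().max())}


def _exp_ring_bifurcation(params, seed, outdir):
    schema = {
        "N": 64, "W0": -0.25, "I0": 0.9, "noise_A": 0.5, "noise_C": 0.25,
        "noise_kind": "pairwise", "n_realizations": 10, "t_end": 400.0,
    }
    p = _validate(params, schema, "ring_bifurcation")
    r0, phi0p = nets.uniform_rate(p["W0"], p["I0"])
    w1cr = 2.0 / phi0p
    cfg = nets.RingConfig(N=p["N"], W0=p["W0"], W1=0.0, I0=p["I0"], t_end=p["t_end"])
    clean = nets.ring_turing_point(cfg, 0.7 * w1cr, 1.4 * w1cr, classifier="growth")
    saddle = nets.ring_saddle_node(cfg, 0.3 * w1cr, 1.4 * w1cr)
    theta = 2.0 * np.pi * np.arange(p["N"]) / p["N"]
    std = np.sqrt(p["noise_A"] + p["noise_C"] * np.cos(theta) ** 2)
    onsets = []
    for rng in _rngs(seed, p["n_realizations"]):
        noise = nets.draw_ring_noise(cfg, rng, std=std, kind=p["noise_kind"])
        onsets.append(nets.ring_turing_point(cfg, 0.4 * w1cr, 1.4 * w1cr, noise=noise))
    pd.DataFrame({"realization": range(len(onsets)), "onset_W1": onsets}).to_csv(
        outdir / "onsets.csv", index=False
    )
    fstats = theory.quenched_fourier_stats(p["noise_A"], 0.0, p["noise_C"], p["N"])
    return {
        "W1_cr_analytic": w1cr,
        "W1_cr_bisection": clean,
        "saddle_node_W1": saddle,
        "mean_noisy_onset": float(np.mean(onsets)),
        "predicted_R_mean": fstats.r_mean,
    }


def _exp_network_capacity(params, seed, outdir):
    schema = {
        "s": 0.2, "M": 30, "n": 100, "P": 0.3, "D": 0.3,
        "W_max": 8.0, "W0": -0.25, "N_list": [16, 64], "replicates": 2,
    }
    p = _validate(params, schema, "network_capacity")
    rows = []
    for N in p["N_list"]:
        for rep in range(p["replicates"]):
            sub = seed + 101 * rep + 13 * N
            W, seq = _learned_system(N, p["M"], p["s"], p["n"], p["P"], p["D"], sub)
            mu, _ = theory.steady_state_moments(MapParams.cosine(p["P"], p["D"]))
            wbar = nets.build_effective_weights(W, mu, p["W_max"], p["W0"])
            cfg = nets.RateNetConfig(kappa=p["s"] * p["M"], W_max=p["W_max"], W0=p["W0"])
            cap = nets.capacity_by_bisection(
                wbar, seq, cfg, np.random.default_rng(sub + 7)
            )
            rows.append((N, rep, cap))
            log.info("network_capacity N=%d rep=%d capacity=%d", N, rep, cap)
    df = pd.DataFrame(rows, columns=["N", "rep", "capacity"])
    df.to_csv(outdir / "capacity.csv", index=False)
    means = df.groupby("N").capacity.mean()
    return {"capacity_by_N": {str(k): float(v) for k, v in means.items()}}


def _exp_mixed_attractors(params, seed, outdir):
    schema = {
        "N": 64, "M": 12, "s": 0.5, "n": 60, "P": 0.3, "D": 0.3,
        "W_max": 40.0, "W0": -0.25, "eta_list": list(range(0, 20)),
    }
    p = _validate(params, schema, "mixed_attractors")
    W, seq = _learned_system(p["N"], p["M"], p["s"], p["n"], p["P"], p["D"], seed)
    mu, _ = theory.steady_state_moments(MapParams.cosine(p["P"], p["D"]))
    wbar = nets.build_effective_weights(W, mu, p["W_max"], p["W0"])
    cfg = nets.RateNetConfig(kappa=p["s"] * p["M"], W_max=p["W_max"], W0=p["W0"])
    rng = np.random.default_rng(seed + 5)
    rows = []
    for eta in p["eta_list"]:
        env = seq.env_for_age(int(eta))
        ro = nets.seed_and_measure(wbar, seq, env, "large", cfg, rng)
        thr = nets.bump_threshold(ro)
        n_supra = sum(a > thr for a in ro.amplitudes.values())
        rows.append((eta, ro.amplitudes[env], ro.null_amplitude, n_supra))
    df = pd.DataFrame(rows, columns=["eta", "amp", "null", "n_supra"])
    df.to_csv(outdir / "supra.csv", index=False)
    return {"max_n_supra": int(df.n_supra.max()), "n_mixed_states": int((df.n_supra >= 2).sum())}


_EXPERIMENTS = {
    "kernel_fit_compare": _exp_kernel_fit_compare,
    "feedforward_protocol": _exp_feedforward_protocol,
    "recurrent_learning": _exp_recurrent_learning,
    "trace_theory_vs_sim": _exp_trace_theory_vs_sim,
    "snr_capacity": _exp_snr_capacity,
    "ring_bifurcation": _exp_ring_bifurcation,
    "network_capacity": _exp_network_capacity,
    "mixed_attractors": _exp_mixed_attractors,
}


def preset_configs() -> dict[str, dict]:
    """Smoke presets: every experiment at a scale completing in well under
    two minutes on one CPU."""
    presets = {name: {} for name in _EXPERIMENTS}
    presets["trace_theory_vs_sim"] = {"replicates": 4, "eta_max": 3}
    presets["ring_bifurcation"] = {"n_realizations": 4}
    presets["mixed_attractors"] = {"eta_list": list(range(0, 12, 2))}
    return presets


def run_experiment(config: ExperimentConfig) -> Path:
    """Execute one experiment; deterministic given the seed.

    Writes results, ``manifest.json`` and ``summary.json`` into the output
    directory; on any error partial outputs are removed and the error
    re-raised.
    """
    if config.experiment not in _EXPERIMENTS:
        raise ExperimentError(
            f"unknown experiment {config.experiment!r} (field: experiment); "
            f"known: {sorted(_EXPERIMENTS)}"
        )
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("experiment=%s seed=%d", config.experiment, config.seed)
        summary = _EXPERIMENTS[config.experiment](
            config.parameters, config.seed, outdir
        )
        manifest = {
            "experiment": config.experiment,
            "seed": config.seed,
            "parameters": config.parameters,
            "package_version": __version__,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
        log.info("done: %s", summary)
        return outdir
    except Exception:
        log.removeHandler(handler)
        handler.close()
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for name in ("manifest.json", "summary.json"):
                (outdir / name).unlink(missing_ok=True)
        raise
    finally:
        if handler in log.handlers:
            log.removeHandler(handler)
            handler.close()


def summarize(result_dir) -> str:
    """Human-readable report of a finished run."""
    result_dir = Path(result_dir)
    manifest_path = result_dir / "manifest.json"
    if not manifest_path.exists():
        raise ExperimentError(f"no manifest in {result_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        f"experiment : {manifest['experiment']}",
        f"seed       : {manifest['seed']}",
        f"version    : {manifest['package_version']}",
    ]
    summary_path = result_dir / "summary.json"
    missing = []
    if summary_path.exists():
        summary = json.loads(summary_path.read_text())
        lines.append("summary:")
        for key, val in summary.items():
            lines.append(f"  {key}: {val}")
    else:
        missing.append(str(summary_path))
    curves = result_dir / "curves.csv"
    if manifest["experiment"] == "trace_theory_vs_sim":
        if curves.exists():
            df = pd.read_csv(curves)
            lines.append("theory vs simulation (amplitude):")
            for _, row in df.iterrows():
                flag = "within band" if row.a_within_band else "OUTSIDE BAND"
                lines.append(
                    f"  eta={int(row.eta):2d}  a_emp={row.a_emp_mean:8.4f}"
                    f"  a_theory={row.a_theory:8.4f}  {flag}"
                )
        else:
            missing.append(str(curves))
    if missing:
        lines.append("missing files:")
        lines.extend(f"  {m}" for m in missing)
    return "\n".join(lines)
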