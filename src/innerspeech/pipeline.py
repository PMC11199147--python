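"""End-to-end orchestration: simulate -> rates -> tuning -> decoding ->
cross-phase -> online -> dPCA -> report, from a single JSON config.

Every stochastic stage derives its own seed from the master seed by a fixed
counter scheme (``stage_seed``), so toggling or adding a stage never
perturbs the randomness of earlier stages, and the same config always
reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .session import (
    TaskConfig,
    exclude_error_trials,
    write_session,
    read_session,
)
from .simulate import PopulationSpec, inject_errors, sample_population, simulate_session
from .rates import bin_spike_counts, phase_average, smooth_rates
from .tuning import (
    DEFAULT_PHASE_PAIRS,
    compare_phase_tuning,
    fit_word_regression,
    tuned_fraction_summary,
)
from .decoding import (
    cross_phase_matrix,
    decode_phase,
    shuffle_significance,
    simulate_online,
)
from .dpca import build_balanced_tensor, fit_dpca, select_lambda, variance_and_projections

#: fixed stage enumeration for the seed counter scheme
STAGES = ("simulate", "errors", "decoding", "online", "dpca")


def stage_seed(master_seed: int, stage: str, counter: int = 0) -> int:
    """Derive a per-stage seed: hash of (master, stage name, counter).

    Deterministic, stage-order independent, and below 2**31.
    """
    h = hashlib.sha256(f"{master_seed}:{stage}:{counter}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Declarative configuration for one full pipeline run."""

    output_dir: str = "run"
    master_seed: int = 0
    n_sessions: int = 4
    n_reps: int = 8
    cue_modalities: tuple[str, ...] = ("written",)
    n_units: int = 32
    area: str = "SMG"
    effect_mean: float = 5.0
    effect_sd: float = 2.0
    p_error_internal: float = 0.0
    p_error_vocalized: float = 0.0
    n_shuffles: int = 100
    online_runs: int = 3
    online_reps_per_run: int = 8
    dpca_lambdas: tuple[float, ...] = (1e-7, 1e-6, 1e-5, 1e-4, 1e-3)
    dpca_folds: int = 10
    dpca_q: int = 3
    stages: dict = field(
        default_factory=lambda: {
            "tuning": True,
            "decoding": True,
            "crossphase": True,
            "online": True,
            "dpca": True,
        }
    )
    task: dict = field(default_factory=dict)  # TaskConfig overrides

    def task_config(self) -> TaskConfig:
        return TaskConfig(**self.task) if self.task else TaskConfig()

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as f:
            d = json.load(f)
        if "cue_modalities" in d:
            d["cue_modalities"] = tuple(d["cue_modalities"])
        if "dpca_lambdas" in d:
            d["dpca_lambdas"] = tuple(d["dpca_lambdas"])
        return cls(**d)


def _simulate_sessions(cfg: PipelineConfig, config: TaskConfig, out: Path) -> list[Path]:
    spec = PopulationSpec(
        n_units=cfg.n_units,
        area=cfg.area,
        effect_mean=cfg.effect_mean,
        effect_sd=cfg.effect_sd,
        seed=stage_seed(cfg.master_seed, "simulate", 10_000),
    )
    paths = []
    sess_dir = out / "sessions"
    sess_dir.mkdir(parents=True, exist_ok=True)
    for s in range(cfg.n_sessions):
        pop = sample_population(
            PopulationSpec(
                **{**asdict(spec), "seed": stage_seed(cfg.master_seed, "simulate", s)}
            ),
            config,
        )
        trials, spikes, gt = simulate_session(
            pop,
            config,
            n_reps=cfg.n_reps,
            cue_modalities=cfg.cue_modalities,
            seed=stage_seed(cfg.master_seed, "simulate", 100 + s),
            session_id=f"sim-{s:03d}",
        )
        if cfg.p_error_internal or cfg.p_error_vocalized:
            trials = inject_errors(
                trials,
                cfg.p_error_internal,
                cfg.p_error_vocalized,
                seed=stage_seed(cfg.master_seed, "errors", s),
            )
        path = sess_dir / f"session_{s:03d}.h5"
        write_session(path, config, trials, spikes, ground_truth=gt)
        paths.append(path)
    return paths


def session_phase_rates(path, config: TaskConfig | None = None):
    """Load a session archive and return (config, clean trials, PhaseRates)."""
    cfg, trials, spikes, _ = read_session(path)
    config = config or cfg
    trials, spikes, _ = exclude_error_trials(trials, spikes)
    tensor = smooth_rates(
        bin_spike_counts(spikes, trials, config), config.kernel_width
    )
    return config, trials, phase_average(tensor, trials, config), tensor


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute enabled stages in dependency order; returns the run directory.

    Artifacts: session archives, tidy CSV tables per stage, a manifest with
    versions/seeds/input hashes, and a human-readable markdown report.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = cfg.task_config()
    manifest: dict = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "config": json.loads(cfg.to_json()),
        "stage_seeds": {},
        "session_hashes": {},
    }

    paths = _simulate_sessions(cfg, config, out)
    for p in paths:
        manifest["session_hashes"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()

    per_session = []
    for p in paths:
        _, trials, pr, tensor = session_phase_rates(p, config)
        per_session.append((p, trials, pr, tensor))

    words = list(config.words)
    phases = list(config.phase_names)

    if cfg.stages.get("tuning", True):
        fractions = []
        for _, _, pr, _ in per_session:
            res = fit_word_regression(pr, config, granularity="per_phase")
            fractions.append(res.tuned_fraction())
        frac = np.array(fractions)
        summary = tuned_fraction_summary(frac, index=phases)
        summary.to_csv(out / "tuning_summary.csv")
        if len(per_session) >= 2:
            compare_phase_tuning(
                pd.DataFrame(frac, columns=phases), DEFAULT_PHASE_PAIRS
            ).to_csv(out / "tuning_phase_comparison.csv", index=False)

    if cfg.stages.get("decoding", True):
        rows = []
        conf_dir = out / "confusions"
        conf_dir.mkdir(exist_ok=True)
        for si, (p, _, pr, _) in enumerate(per_session):
            for phase in phases:
                res = decode_phase(pr, phase, classes=words)
                shuf = shuffle_significance(
                    pr.rates[phase],
                    pr.labels["word"].to_numpy(object),
                    n_shuffles=cfg.n_shuffles,
                    seed=stage_seed(cfg.master_seed, "decoding", si * 10 + phases.index(phase)),
                    classes=words,
                    observed=res.accuracy,
                )
                rows.append(
                    {
                        "session": p.name,
                        "phase": phase,
                        "accuracy": res.accuracy,
                        "null_mean": float(shuf.null_accuracies.mean()),
                        "null_p975": shuf.percentile_975,
                        "null_p995": shuf.percentile_995,
                        "grade": shuf.grade,
                    }
                )
                pd.DataFrame(res.confusion, index=res.classes, columns=res.classes).to_csv(
                    conf_dir / f"confusion_{p.stem}_{phase}.csv"
                )
        pd.DataFrame(rows).to_csv(out / "decoding.csv", index=False)

    if cfg.stages.get("crossphase", True):
        mats = []
        for p, _, pr, _ in per_session:
            m = cross_phase_matrix(pr, phases=["ITI", "cue", "internal", "speech"], classes=words)
            mats.append(m)
        mean_mat = sum(mats) / len(mats)
        mean_mat.to_csv(out / "crossphase_matrix.csv")

    if cfg.stages.get("online", True):
        # initial block = first session's internal-phase data; runs simulated fresh
        pop = sample_population(
            PopulationSpec(
                n_units=cfg.n_units,
                area=cfg.area,
                effect_mean=cfg.effect_mean,
                effect_sd=cfg.effect_sd,
                seed=stage_seed(cfg.master_seed, "online", 0),
            ),
            config,
        )

        def run_block(counter):
            trials, spikes, _ = simulate_session(
                pop,
                config,
                n_reps=cfg.online_reps_per_run,
                cue_modalities=("written",),
                seed=stage_seed(cfg.master_seed, "online", counter),
            )
            tensor = smooth_rates(bin_spike_counts(spikes, trials, config), config.kernel_width)
            pr = phase_average(tensor, trials, config)
            return pr.rates["internal"], pr.labels["word"].to_numpy(object)

        X0, y0 = run_block(1)
        runs = [run_block(2 + r) for r in range(cfg.online_runs)]
        res = simulate_online(
            X0, y0, runs, config, classes=words,
            n_shuffles=0, seed=stage_seed(cfg.master_seed, "online", 999),
        )
        online = {
            "run_accuracies": res.run_accuracies,
            "overall_accuracy": res.overall_accuracy,
            "trials_per_word_before_run": res.trials_per_word_before_run,
            "train_seconds_per_word_before_run": res.train_seconds_per_word_before_run,
        }
        (out / "online.json").write_text(json.dumps(online, indent=2))

    if cfg.stages.get("dpca", True):
        p, trials, pr, tensor = per_session[0]
        tt = build_balanced_tensor(tensor, trials, config, k_target=cfg.n_reps)
        lam, table = select_lambda(
            tt,
            cfg.dpca_lambdas,
            folds=cfg.dpca_folds,
            seed=stage_seed(cfg.master_seed, "dpca", 0),
            q=cfg.dpca_q,
        )
        model = fit_dpca(tt, lam=lam, q=cfg.dpca_q)
        ledger, projections = variance_and_projections(model, tt)
        table.to_csv(out / "dpca_lambda_cv.csv", index=False)
        ledger.to_csv(out / "dpca_variance.csv", index=False)
        np.savez(
            out / "dpca_projections.npz",
            **{name: proj for name, proj in projections.items()},
        )
        manifest["dpca_lambda"] = lam

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    generate_report(out)
    return out


def generate_report(run_dir) -> Path:
    """Render a markdown report (+ figures) from whatever artifacts exist.

    Missing stages are listed but do not prevent report generation;
    regeneration is idempotent.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run_dir = Path(run_dir)
    lines = ["# Pipeline report", ""]
    missing = []

    tuning_path = run_dir / "tuning_summary.csv"
    if tuning_path.exists():
        summary = pd.read_csv(tuning_path, index_col=0)
        lines += ["## Word tuning (per phase)", "", summary.to_markdown(), ""]
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(summary.index, summary["mean_pct_tuned"])
        ax.set_ylabel("% tuned units")
        fig.tight_layout()
        fig.savefig(run_dir / "tuning_summary.png", dpi=100)
        plt.close(fig)
        cmp_path = run_dir / "tuning_phase_comparison.csv"
        if cmp_path.exists():
            lines += ["### Rest vs action phases (paired t)", "",
                      pd.read_csv(cmp_path).to_markdown(index=False), ""]
    else:
        missing.append("tuning")

    dec_path = run_dir / "decoding.csv"
    if dec_path.exists():
        dec = pd.read_csv(dec_path)
        agg = dec.groupby("phase", sort=False).agg(
            accuracy=("accuracy", "mean"), null_mean=("null_mean", "mean")
        )
        lines += ["## Word decoding (LOO, shuffle-graded)", "", agg.to_markdown(), ""]
        chance_line = dec["null_mean"].mean()
        lines += [f"Mean shuffle-null accuracy (chance): {chance_line:.1f}%", ""]
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(agg.index, agg["accuracy"])
        ax.axhline(chance_line, color="red", ls="--", label="chance (null mean)")
        ax.set_ylabel("accuracy (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(run_dir / "decoding.png", dpi=100)
        plt.close(fig)
    else:
        missing.append("decoding")

    cp_path = run_dir / "crossphase_matrix.csv"
    if cp_path.exists():
        mat = pd.read_csv(cp_path, index_col=0)
        lines += ["## Cross-phase generalization (train row, test column)", "",
                  mat.to_markdown(), ""]
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(mat.to_numpy(), cmap="viridis")
        ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=45)
        ax.set_yticks(range(len(mat.index)), mat.index)
        fig.colorbar(im, label="accuracy (%)")
        fig.tight_layout()
        fig.savefig(run_dir / "crossphase.png", dpi=100)
        plt.close(fig)
    else:
        missing.append("crossphase")

    online_path = run_dir / "online.json"
    if online_path.exists():
        online = json.loads(online_path.read_text())
        lines += ["## Simulated online decoding", ""]
        for r, (acc, reps, sec) in enumerate(
            zip(
                online["run_accuracies"],
                online["trials_per_word_before_run"],
                online["train_seconds_per_word_before_run"],
            )
        ):
            lines.append(
                f"- run {r + 1}: {acc:.1f}% correct "
                f"(trained on {reps:.0f} trials/word = {sec:.0f} s/word)"
            )
        lines += ["", f"Overall online accuracy: {online['overall_accuracy']:.1f}%", ""]
    else:
        missing.append("online")

    dpca_path = run_dir / "dpca_variance.csv"
    if dpca_path.exists():
        ledger = pd.read_csv(dpca_path)
        shares = ledger.drop_duplicates("marginalization")[
            ["marginalization", "marg_variance_share"]
        ]
        lines += ["## dPCA variance by marginalization", "",
                  shares.to_markdown(index=False), ""]
        proj_path = run_dir / "dpca_projections.npz"
        if proj_path.exists():
            with np.load(proj_path) as npz:
                fig, axes = plt.subplots(1, len(npz.files), figsize=(3 * len(npz.files), 2.5))
                for ax, name in zip(np.atleast_1d(axes), npz.files):
                    proj = npz[name]  # (q, T, C, W)
                    for c in range(proj.shape[2]):
                        for w in range(proj.shape[3]):
                            ax.plot(proj[0, :, c, w], lw=0.8)
                    ax.set_title(name)
                fig.tight_layout()
                fig.savefig(run_dir / "dpca_projections.png", dpi=100)
                plt.close(fig)
    else:
        missing.append("dpca")

    if missing:
        lines += ["## Missing stages", ""] + [f"- {m}" for m in missing] + [""]
    report = run_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
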