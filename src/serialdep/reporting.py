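"""Trial-table I/O, folded-curve summaries, run configuration and the
end-to-end analysis pipeline.

``run_full_analysis`` executes: simulate (or load) a trial table ->
preprocessing cascade -> condition split -> pooled DoG fit per subset ->
sign-shuffle tests of each subset's half-amplitude -> label-shuffle
difference tests (previous low vs high, current low vs high, no-load vs
load) -> residualized error scatter with paired comparisons -> folded
display curves, and emits one structured, self-describing report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .descriptive import (
    RESIDUALIZE_WINDOW,
    error_scatter,
    paired_comparison,
    split_conditions,
)
from .dog import fit_dog
from .inference import label_shuffle_difference, sign_shuffle_test
from .preprocessing import IQR_K, LAPSE_CUTOFF, RT_CUTOFF, preprocess
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "fold_and_smooth",
    "read_trials",
    "write_trials",
    "run_full_analysis",
]

TRIAL_COLUMNS = {
    "participant": None,
    "trial_index": "int64",
    "has_load": "bool",
    "load_level": "object",
    "theta": "float64",
    "reported": "float64",
    "rt": "float64",
}
OPTIONAL_COLUMNS = ("block", "memory_correct", "is_lapse")
LOAD_LEVELS = ("none", "low", "high")


def fold_and_smooth(
    deltas,
    errors,
    smooth_window: float = 10.0,
    grid=None,
) -> pd.DataFrame:
    """Folded serial-bias curve for display.

    Folded error = ``error * sign(delta)`` plotted against ``|delta|``
    (trials at delta == 0 contribute 0).  Returns a running mean and SD of
    the folded errors within ``smooth_window / 2`` degrees of each grid
    point (full boxcar span ``smooth_window``), with the window clipped at
    the ends of the folded axis.  Display-only; inference always runs on
    the unfolded errors.
    """
    if not smooth_window > 0:
        raise ValueError("smooth_window must be positive")
    d = np.asarray(deltas, dtype=float).ravel()
    e = np.asarray(errors, dtype=float).ravel()
    if d.shape != e.shape:
        raise ValueError("deltas and errors must have the same length")
    folded = e * np.sign(d)
    x = np.abs(d)
    if grid is None:
        grid = np.arange(0.0, 90.0 + 0.5, 1.0)
    grid = np.asarray(grid, dtype=float)
    mean = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    count = np.zeros(grid.shape, dtype=int)
    for i, g in enumerate(grid):
        sel = np.abs(x - g) <= smooth_window / 2.0
        count[i] = int(sel.sum())
        if count[i] > 0:
            mean[i] = folded[sel].mean()
        if count[i] > 1:
            sd[i] = folded[sel].std(ddof=1)
    return pd.DataFrame(
        {"abs_delta": grid, "folded_mean": mean, "folded_sd": sd, "n": count}
    )


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (lossless round-trip with :func:`read_trials`)."""
    trials.to_csv(path, index=False)


def read_trials(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    ``column_map`` renames foreign column names to the canonical schema
    (``{"their_name": "canonical_name"}``), absorbing deposited datasets
    with different headers.  Raises ``ValueError`` naming offending rows
    for out-of-range orientations or non-positive response times; a
    missing ``memory_correct`` on no-load trials is accepted as
    not-applicable.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table {path} is missing columns: {missing}")
    for col, dtype in TRIAL_COLUMNS.items():
        if dtype is not None:
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"column {col!r} is not convertible to {dtype}: {exc}")
    bad_theta = df.index[(df["theta"] <= 0) | (df["theta"] > 180)].tolist()
    if bad_theta:
        raise ValueError(
            f"theta out of (0, 180] at rows {bad_theta[:10]}"
            + ("..." if len(bad_theta) > 10 else "")
        )
    bad_rt = df.index[df["rt"] <= 0].tolist()
    if bad_rt:
        raise ValueError(f"non-positive rt at rows {bad_rt[:10]}")
    bad_level = df.index[~df["load_level"].isin(LOAD_LEVELS)].tolist()
    if bad_level:
        raise ValueError(f"unknown load_level at rows {bad_level[:10]}")
    if "memory_correct" in df.columns:
        df["memory_correct"] = (
            df["memory_correct"]
            .map({True: True, False: False, "True": True, "False": False})
            .astype("boolean")
        )
    else:
        df["memory_correct"] = pd.array([pd.NA] * len(df), dtype="boolean")
    if "is_lapse" in df.columns:
        df["is_lapse"] = df["is_lapse"].astype(bool)
    return df


@dataclass
class RunConfig:
    """Configuration of a full analysis run; round-trips through YAML."""

    sim: SimConfig | None = None          # generate data ...
    input_path: str | None = None         # ... or load them
    column_map: dict | None = None
    lapse_cutoff: float = LAPSE_CUTOFF
    iqr_k: float = IQR_K
    rt_cutoff: float = RT_CUTOFF
    residualize_window: float = RESIDUALIZE_WINDOW
    smooth_window: float = 10.0
    n_perm: int = 10000
    n_boot: int = 1000
    seed: int = 0
    output_dir: str | None = None
    make_figures: bool = False

    def __post_init__(self):
        if self.sim is None and self.input_path is None:
            self.sim = SimConfig()
        if isinstance(self.sim, dict):
            self.sim = SimConfig.from_dict(self.sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)


_CONTRASTS = (
    ("prev_low_vs_prev_high", "prev_low", "prev_high"),
    ("curr_low_vs_curr_high", "curr_low", "curr_high"),
    ("no_load_vs_load", "no_load", "load"),
)


def run_full_analysis(config: RunConfig, trials: pd.DataFrame | None = None) -> dict:
    """Execute the full pipeline and return a structured report dict.

    If ``config.output_dir`` is set, writes ``report.json``, the cleaned
    trial table and per-subset folded curves (plus figures when
    ``make_figures``).
    """
    seeds = np.random.SeedSequence(config.seed).generate_state(8) % (2**31 - 1)
    if trials is None:
        if config.input_path is not None:
            trials = read_trials(config.input_path, config.column_map)
        else:
            trials = generate_dataset(config.sim)

    cleaned = preprocess(
        trials,
        lapse_cutoff=config.lapse_cutoff,
        iqr_k=config.iqr_k,
        rt_cutoff=config.rt_cutoff,
    )
    split = split_conditions(cleaned)

    report: dict = {
        "config": config.to_dict(),
        "n_trials": int(cleaned.n_trials),
        "exclusions": {k: int(v) for k, v in cleaned.exclusion_counts.items()},
        "exclusion_fraction": cleaned.exclusion_fraction,
        "subset_counts": split.counts,
        "fits": {},
        "sign_shuffle": {},
        "label_shuffle": {},
        "scatter": {},
        "seeds": {"root": int(config.seed)},
    }

    folded = {}
    for i, name in enumerate(("prev_low", "prev_high", "curr_low", "curr_high",
                              "no_load", "load")):
        sub = split[name]
        d = sub["delta"].to_numpy()
        e = sub["error_clean"].to_numpy()
        fit = fit_dog(d, e)
        report["fits"][name] = fit.to_dict()
        sseed = int(seeds[0]) + i
        perm = sign_shuffle_test(d, e, n_perm=config.n_perm, seed=sseed)
        report["sign_shuffle"][name] = {
            "alpha": perm["alpha"].to_dict(),
            "w": perm["w"].to_dict(),
        }
        report["seeds"][f"sign_shuffle_{name}"] = sseed
        folded[name] = fold_and_smooth(d, e, smooth_window=config.smooth_window)

    for j, (cname, a, b) in enumerate(_CONTRASTS):
        sa, sb = split[a], split[b]
        lseed = int(seeds[1]) + j
        diff = label_shuffle_difference(
            sa["delta"].to_numpy(), sa["error_clean"].to_numpy(),
            sb["delta"].to_numpy(), sb["error_clean"].to_numpy(),
            n_perm=config.n_perm, seed=lseed,
        )
        report["label_shuffle"][cname] = {
            "alpha_diff": diff["alpha_diff"].to_dict(),
            "w_diff": diff["w_diff"].to_dict(),
        }
        report["seeds"][f"label_shuffle_{cname}"] = lseed

    if "memory_correct" in trials.columns:
        mem = trials[trials["load_level"].isin(["low", "high"])].copy()
        mem["memory_correct"] = mem["memory_correct"].astype("boolean").astype("Float64")
        pc = (
            mem.groupby(["participant", "load_level"], observed=True)["memory_correct"]
            .mean()
            .unstack()
        )
        if {"low", "high"} <= set(pc.columns) and len(pc.dropna()) >= 3:
            pc = pc.dropna()
            report["memory"] = {
                "pc_low_mean": float(pc["low"].mean()),
                "pc_low_sd": float(pc["low"].std(ddof=1)),
                "pc_high_mean": float(pc["high"].mean()),
                "pc_high_sd": float(pc["high"].std(ddof=1)),
                "test_low_vs_high": paired_comparison(
                    pc["low"].to_numpy(dtype=float), pc["high"].to_numpy(dtype=float)
                ).to_dict(),
            }

    scatter = error_scatter(cleaned, window=config.residualize_window)
    wide = scatter.pivot(index="participant", columns="condition", values="scatter")
    for cond in ("no_load", "low", "high", "load"):
        if cond in wide:
            vals = wide[cond].dropna()
            report["scatter"][cond] = {
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
                "n_participants": int(len(vals)),
            }
    for cname, a, b in (("no_load_vs_load", "no_load", "load"),
                        ("low_vs_high", "low", "high")):
        if a in wide and b in wide:
            paired = wide[[a, b]].dropna()
            if len(paired) >= 3:
                test = paired_comparison(paired[a].to_numpy(), paired[b].to_numpy())
                report["scatter"][f"test_{cname}"] = test.to_dict()

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        cleaned.data.to_csv(out / "cleaned_trials.csv", index=False)
        scatter.to_csv(out / "scatter.csv", index=False)
        for name, curve in folded.items():
            curve.to_csv(out / f"folded_{name}.csv", index=False)
        if config.make_figures:
            _plot_folded(folded, report["fits"], out / "folded_curves.png")
        logger.info("report written to %s", out)

    report["_folded"] = folded  # in-memory only; not serialized above
    return report


def _plot_folded(folded: dict, fits: dict, path) -> None:
    """Folded-error display curves with the fitted DoG overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .dog import dog_curve

    names = [n for n in folded if n not in ("no_load", "load")] or list(folded)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.2),
                             sharey=True, squeeze=False)
    for ax, name in zip(axes[0], names):
        curve = folded[name]
        ax.plot(curve["abs_delta"], curve["folded_mean"], lw=1.5, label="folded mean")
        ax.fill_between(
            curve["abs_delta"],
            curve["folded_mean"] - curve["folded_sd"],
            curve["folded_mean"] + curve["folded_sd"],
            alpha=0.2,
        )
        f = fits[name]
        xs = np.linspace(0, 90, 181)
        ax.plot(xs, dog_curve(xs, f["alpha"], f["w"]), "k--", lw=1,
                label=f"DoG α={f['alpha']:.2f}, w={f['w']:.3f}")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(name)
        ax.set_xlabel("|Δ| (deg)")
        ax.legend(fontsize=7)
    axes[0][0].set_ylabel("folded error (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
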