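"""Grid orchestration: seeded repetitions over the full condition grid,
long-format result tables, and summary tables/plots.

Seeding
-------
Every repetition derives its random state from a
``numpy.random.SeedSequence`` keyed on
``(base_seed, K, p, round(1000 * D_KL), N, rep_index)``.  The number of
ordinal categories is deliberately *not* part of the key: within a
repetition the same mixture design and the same continuous sample are
reused across all category counts (and the continuous condition), so that
varying ``c`` isolates the effect of the discretisation, mirroring how a
single cloud of continuous draws is thresholded at every granularity.  The
EM initialisation stream additionally keys on ``c`` and the model family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import Condition, build_design
from .estimate import EMConfig, ModelFamily, select_k
from .evaluate import RecoveryMetrics, score_repetition, summarize_cell
from .simulate import discretize, sample_mixture

__all__ = [
    "GridConfig",
    "run_repetition",
    "run_grid",
    "make_summaries",
    "enumerate_conditions",
]

_RESULT_COLUMNS = [
    "K", "p", "target_kl", "N", "n_categories", "family", "rep",
    "K_true", "K_hat", "correct", "mae_means", "mae_variances",
    "mae_covariances", "mae_weights", "n_failed_K", "seed_key", "error",
]


@dataclass
class GridConfig:
    """Declarative description of a simulation grid.

    ``c_values`` may mix integers and the sentinel ``"continuous"``.  The
    paper-scale grid is K x p x D_KL x N x c =
    3 x 9 x 3 x 3 x 12 = 2916 conditions at 100 repetitions each; scaled-down
    grids simply list fewer values or repetitions.
    """

    K_values: tuple = (2, 3, 4)
    p_values: tuple = tuple(range(2, 11))
    kl_values: tuple = (2.0, 3.5, 5.0)
    N_values: tuple = (1000, 2500, 10000)
    c_values: tuple = ("continuous", 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12)
    family: str = "shared_spherical"
    reps: int = 100
    base_seed: int = 0
    K_max: int = 7
    n_init: int = 10
    max_iter: int = 500
    tol: float = 1e-8
    output_dir: str = "results"
    jobs: int = 1
    freeze_design: bool = False  # reuse one design across repetitions

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("K_values", "p_values", "kl_values", "N_values",
                     "c_values"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def em_config(self, seed: int = 0) -> EMConfig:
        return EMConfig(n_init=self.n_init, max_iter=self.max_iter,
                        tol=self.tol, seed=seed)


def enumerate_conditions(config: GridConfig) -> list:
    """All grid cells of a config, in a stable order."""
    out = []
    for K, p, kl, N, c in itertools.product(
        config.K_values, config.p_values, config.kl_values,
        config.N_values, config.c_values,
    ):
        out.append(Condition(K=K, p=p, target_kl=float(kl), N=N,
                             n_categories=c, family=config.family,
                             reps=config.reps, base_seed=config.base_seed))
    return out


def _seed_sequence(condition: Condition, rep_index: int) -> np.random.SeedSequence:
    # Stable integer key; c and family excluded so the continuous sample is
    # shared across category counts within a repetition.
    return np.random.SeedSequence(
        [int(condition.base_seed), condition.K, condition.p,
         int(round(1000 * float(condition.target_kl))), condition.N,
         rep_index],
    )


def _em_seed(condition: Condition, rep_index: int) -> int:
    c_code = 0 if condition.is_continuous else int(condition.n_categories)
    fam_code = 1 if condition.family == "full_unconstrained" else 0
    ss = np.random.SeedSequence(
        [int(condition.base_seed), condition.K, condition.p,
         int(round(1000 * float(condition.target_kl))), condition.N,
         rep_index, c_code, fam_code, 1],
    )
    return int(ss.generate_state(1)[0] % (2**31))


def run_repetition(condition: Condition, rep_index: int,
                   em_config: EMConfig | None = None,
                   K_max: int = 7,
                   freeze_design: bool = False) -> dict:
    """Execute one repetition of one grid cell.

    Pipeline: build a (freshly randomised) design, draw the continuous
    sample, discretise unless the condition is continuous, select K by BIC,
    and score recovery.  Fully deterministic given
    ``(base_seed, condition, rep_index)``.  Any stage error is recorded in
    the returned row rather than raised.
    """
    design_rep = 0 if freeze_design else rep_index
    ss = _seed_sequence(condition, design_rep)
    design_ss, sample_ss = ss.spawn(2)
    row = {
        "K": condition.K, "p": condition.p,
        "target_kl": float(condition.target_kl), "N": condition.N,
        "n_categories": str(condition.n_categories),
        "family": condition.family, "rep": rep_index,
        "K_true": condition.K, "K_hat": np.nan, "correct": False,
        "mae_means": np.nan, "mae_variances": np.nan,
        "mae_covariances": np.nan, "mae_weights": np.nan,
        "n_failed_K": 0, "seed_key": int(ss.generate_state(1)[0] % (2**31)),
        "error": "",
    }
    try:
        design = build_design(condition, np.random.default_rng(design_ss))
        sample_seed = int(
            np.random.SeedSequence(
                [int(condition.base_seed), condition.K, condition.p,
                 int(round(1000 * float(condition.target_kl))), condition.N,
                 rep_index, 2],
            ).generate_state(1)[0] % (2**31)
        )
        sample = sample_mixture(design, condition.N, sample_seed)
        if condition.is_continuous:
            data = sample.values
        else:
            data = discretize(sample, int(condition.n_categories)).values
        base_cfg = em_config or EMConfig()
        cfg = EMConfig(n_init=base_cfg.n_init, max_iter=base_cfg.max_iter,
                       tol=base_cfg.tol,
                       seed=_em_seed(condition, rep_index),
                       variance_count=base_cfg.variance_count)
        sel = select_k(data, ModelFamily(condition.family), K_max=K_max,
                       config=cfg)
        metrics = score_repetition(design, sel.K_hat, sel.selected)
        row.update({
            "K_hat": sel.K_hat, "correct": metrics.correct,
            "n_failed_K": sum(f.failed for f in sel.fits),
        })
        if metrics.correct:
            row.update({
                "mae_means": metrics.mae_means,
                "mae_variances": metrics.mae_variances,
                "mae_covariances": metrics.mae_covariances,
                "mae_weights": metrics.mae_weights,
            })
    except Exception as exc:  # repetition failures must not abort the grid
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


def _row_key(row: dict) -> tuple:
    return (row["K"], row["p"], row["target_kl"], row["N"],
            str(row["n_categories"]), row["family"], row["rep"])


def run_grid(config: GridConfig, progress: bool = False) -> pd.DataFrame:
    """Run every (condition x repetition) cell of the grid.

    Results are appended incrementally to ``<output_dir>/results.csv``;
    rerunning with the same config resumes, skipping rows already present,
    and yields a table identical to an uninterrupted run.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "results.csv"

    done = set()
    existing = None
    if csv_path.exists():
        existing = pd.read_csv(csv_path)
        existing["n_categories"] = existing["n_categories"].astype(str)
        existing["error"] = (
            existing["error"].fillna("").astype(str)
            if "error" in existing else ""
        )
        for _, r in existing.iterrows():
            done.add(_row_key(r))

    conditions = enumerate_conditions(config)
    tasks = [
        (cond, rep)
        for cond in conditions
        for rep in range(config.reps)
        if _row_key({
            "K": cond.K, "p": cond.p, "target_kl": float(cond.target_kl),
            "N": cond.N, "n_categories": str(cond.n_categories),
            "family": cond.family, "rep": rep,
        }) not in done
    ]

    def _one(cond, rep):
        return run_repetition(cond, rep, em_config=config.em_config(),
                              K_max=config.K_max,
                              freeze_design=config.freeze_design)

    rows = []
    if config.jobs > 1 and tasks:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=config.jobs)(
            delayed(_one)(cond, rep) for cond, rep in tasks
        )
    else:
        for i, (cond, rep) in enumerate(tasks):
            rows.append(_one(cond, rep))
            if progress and (i + 1) % 10 == 0:
                print(f"  {i + 1}/{len(tasks)} repetitions done", flush=True)

    new = pd.DataFrame(rows, columns=_RESULT_COLUMNS)
    if existing is not None and len(existing):
        table = pd.concat([existing, new], ignore_index=True)
    else:
        table = new
    table = table.sort_values(
        ["family", "K", "p", "target_kl", "N", "n_categories", "rep"]
    ).reset_index(drop=True)
    table.to_csv(csv_path, index=False)
    return table


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def accuracy_by_p_c(table: pd.DataFrame, N: int) -> pd.DataFrame:
    """Accuracy averaged over K and D_KL, one row per p, one column per c.

    Cell accuracies are averaged unweighted across the (K, D_KL) cells,
    which coincides with pooling repetitions when cells have equal reps.
    """
    sub = table[table["N"] == N]
    cell = (
        sub.groupby(["p", "n_categories", "K", "target_kl"])["correct"]
        .mean()
        .reset_index()
    )
    piv = cell.pivot_table(index="p", columns="n_categories",
                           values="correct", aggfunc="mean")
    return piv.round(2)


def khat_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Counts of the selected K per (p, c) cell (box-plot source data)."""
    sub = table.dropna(subset=["K_hat"])
    return (
        sub.groupby(["p", "n_categories", "K_hat"])
        .size()
        .rename("count")
        .reset_index()
    )


def error_by_p_c(table: pd.DataFrame, N: int,
                 what: str = "mae_means") -> pd.DataFrame:
    """Parameter error averaged over K and D_KL in correct repetitions only;
    cells where no repetition selected the correct K stay missing."""
    sub = table[(table["N"] == N) & table["correct"].astype(bool)]
    cell = (
        sub.groupby(["p", "n_categories", "K", "target_kl"])[what]
        .mean()
        .reset_index()
    )
    piv = cell.pivot_table(index="p", columns="n_categories",
                           values=what, aggfunc="mean")
    return piv.round(2)


def _heatmap(piv: pd.DataFrame, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.7 * piv.shape[1],
                                    1 + 0.5 * piv.shape[0]))
    im = ax.imshow(piv.values, cmap="viridis", aspect="auto")
    ax.set_xticks(range(piv.shape[1]), [str(c) for c in piv.columns])
    ax.set_yticks(range(piv.shape[0]), [str(i) for i in piv.index])
    ax.set_xlabel("number of ordinal categories c")
    ax.set_ylabel("number of variables p")
    ax.set_title(title)
    for i in range(piv.shape[0]):
        for j in range(piv.shape[1]):
            v = piv.values[i, j]
            if np.isfinite(v):
                ax.text(j, i, f"{v:.2f}", ha="center", va="center",
                        color="white", fontsize=8)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def make_summaries(table: pd.DataFrame, output_dir) -> dict:
    """Write per-N accuracy heatmaps (c x p, averaged over K and D_KL),
    K-hat distribution tables, and parameter-error heatmaps, as CSV + PNG.

    Returns the summary frames keyed by file stem.
    """
    if table.empty:
        raise ValueError("empty results table")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for N in sorted(table["N"].unique()):
        acc = accuracy_by_p_c(table, N)
        acc.to_csv(outdir / f"accuracy_p_by_c_N{N}.csv")
        _heatmap(acc, f"Accuracy (avg over K, D_KL), N={N}",
                 outdir / f"accuracy_p_by_c_N{N}.png")
        out[f"accuracy_p_by_c_N{N}"] = acc
        for what in ("mae_means", "mae_variances", "mae_covariances"):
            err = error_by_p_c(table, N, what)
            err.to_csv(outdir / f"{what}_p_by_c_N{N}.csv")
            if err.size:
                _heatmap(err, f"{what} (correct reps), N={N}",
                         outdir / f"{what}_p_by_c_N{N}.png")
            out[f"{what}_p_by_c_N{N}"] = err
    kd = khat_distribution(table)
    kd.to_csv(outdir / "khat_distribution.csv", index=False)
    out["khat_distribution"] = kd
    return out
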