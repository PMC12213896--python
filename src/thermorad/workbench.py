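"""Study orchestration and command-line interface.

Ties the pipeline together: sample cohorts, resolve a grid of matched
RT/HT/combined schedule pairs, simulate every (tumour, schedule) combination,
compute response metrics and stratification, apply the comparison rules and
write the tabular outputs plus a run manifest.

Outputs (all plain text):

* ``cohort_<REGIME>.csv`` — id, regime, q1, q3, V0, T_star, c_star
* ``responses.csv`` — one row per (tumour, schedule pair, treatment) with the
  four percent-change metrics, combined score, response class and
  deleterious flag
* ``comparison.csv`` — per (tumour, schedule pair): the three combined
  scores, rule outcomes and the winning treatment
* ``ranked.json`` — per-tumour best treatment/regimen and full ranking
* ``manifest.json`` — seeds, thresholds, solver tolerances, flag values
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import __version__
from .cohorts import (
    Cohort,
    VirtualTumour,
    read_cohort_csv,
    sample_cohort,
    write_cohort_csv,
)
from .comparison import (
    MatchedTriple,
    best_treatment,
    rank_regimens,
    rule1_ineffective,
)
from .equilibria import (
    NoRootError,
    RegimeLabel,
    classify_regime,
    nl_fixed_point,
    q1_threshold,
    q3_threshold,
    sl_fixed_point,
)
from .model_core import ModelParams
from .response_metrics import percent_changes, stratify_cohort
from .schedules import (
    BETA_MAX,
    Schedule,
    build_combined,
    build_ht_schedule,
    build_rt_schedule,
)
from .simulate import SolverOptions, last_week_means, simulate

__all__ = [
    "RunConfig",
    "fixtures",
    "build_pair_grid",
    "run_sweep",
    "attach_response_classes",
    "compare_from_responses",
    "run_study",
    "main",
]

#: (q3, q1) for the six representative tumours; A1-C1 are NL (V0 = 0.0005),
#: A2-C2 are SL (V0 = 0.005).
_FIXTURE_PARAMS = {
    "A1": (0.272, 0.503, 0.0005),
    "B1": (0.0401, 7.78, 0.0005),
    "C1": (9.94, 7.60, 0.0005),
    "A2": (0.210, 0.151, 0.005),
    "B2": (0.143, 2.14, 0.005),
    "C2": (7.61, 2.14, 0.005),
}


def fixtures(params: ModelParams | None = None) -> dict[str, VirtualTumour]:
    """The six representative tumours with verified regimes and baselines."""
    out = {}
    for i, (name, (q3, q1, V0)) in enumerate(_FIXTURE_PARAMS.items()):
        regime = classify_regime(q1, q3, V0, params)
        fp = (
            sl_fixed_point(q1, q3, V0, params)
            if regime is RegimeLabel.SL
            else nl_fixed_point(q1, q3, V0, params)
        )
        out[name] = VirtualTumour(
            id=i, q1=q1, q3=q3, V0=V0, regime=regime,
            T_star=fp.T_star, c_star=fp.c_star,
        )
    return out


@dataclass
class RunConfig:
    """Fully serialisable description of one study run."""

    cohorts: list[dict] = field(
        default_factory=lambda: [
            {"regime": "NL", "N": 50, "seed": 1},
            {"regime": "SL", "N": 50, "seed": 2},
            {"regime": "BS", "N": 50, "seed": 3},
        ]
    )
    rt_grid: list[list] = field(default_factory=lambda: [[2.0, 5]])
    beta_grid: list[float] = field(default_factory=lambda: [0.005])
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"
    rule2_mode: str = "better"
    include_nonnegative_percentiles: bool = False
    outdir: str = "study_out"
    parameter_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def solver_options(self) -> SolverOptions:
        return SolverOptions(method=self.method, rtol=self.rtol, atol=self.atol)

    def base_params(self) -> ModelParams:
        if self.parameter_overrides:
            base = ModelParams().to_mapping()
            base.update(self.parameter_overrides)
            return ModelParams.from_mapping(base)
        return ModelParams()


def build_pair_grid(
    rt_grid: list[list], beta_grid: list[float]
) -> list[tuple[Schedule, Schedule, Schedule]]:
    """Matched (RT, HT, combined) schedule triples for every grid point.

    The HT plan inherits the RT plan's duration; grid points whose total
    thermal dose would exceed the cap are dropped.
    """
    pairs = []
    for D, N_frac in rt_grid:
        rt = build_rt_schedule(float(D), int(N_frac))
        for beta in beta_grid:
            if beta * rt.N_wks > BETA_MAX + 1e-12:
                continue
            ht = build_ht_schedule(float(beta), rt.N_wks)
            combo = build_combined(float(D), int(N_frac), float(beta))
            pairs.append((rt, ht, combo))
    return pairs


def _simulate_response(tumour, schedule, treatment, options, params):
    traj = simulate(tumour, schedule, options, params)
    means = last_week_means(traj, schedule)
    return percent_changes(means, tumour, treatment)


def run_sweep(
    cohort: Cohort,
    pairs: list[tuple[Schedule, Schedule, Schedule]],
    options: SolverOptions | None = None,
    params: ModelParams | None = None,
    on_error: str = "skip",
) -> pd.DataFrame:
    """Simulate every tumour under every schedule of every matched pair.

    Simulations are cached per (tumour, schedule descriptor), so HT plans
    shared between pairs run once.  A failing integration excludes that
    tumour/schedule row (logged in the frame's ``attrs``) unless
    ``on_error="raise"``.
    """
    rows = []
    failures = []
    for tumour in cohort.tumours:
        cache: dict[str, object] = {}
        for rt, ht, combo in pairs:
            pair_key = (rt.describe(), ht.describe())
            for treatment, schedule in (("R", rt), ("H", ht), ("R_H", combo)):
                desc = schedule.describe()
                if desc not in cache:
                    try:
                        cache[desc] = _simulate_response(
                            tumour, schedule, treatment, options, params
                        )
                    except RuntimeError as exc:
                        if on_error == "raise":
                            raise
                        failures.append(
                            {"tumour": tumour.id, "schedule": desc,
                             "error": str(exc)}
                        )
                        cache[desc] = None
                summary = cache[desc]
                if summary is None:
                    continue
                rows.append(
                    {
                        "cohort": cohort.regime.value,
                        "tumour_id": tumour.id,
                        "q1": tumour.q1,
                        "q3": tumour.q3,
                        "V0": tumour.V0,
                        "T_star": tumour.T_star,
                        "c_star": tumour.c_star,
                        "pair_rt": pair_key[0],
                        "pair_ht": pair_key[1],
                        "treatment": treatment,
                        "schedule": desc,
                        "D": schedule.D,
                        "N_frac": schedule.N_frac,
                        "beta_tilde": schedule.beta_tilde,
                        "N_wks": schedule.N_wks,
                        "delta_viable": summary.delta_viable,
                        "delta_total": summary.delta_total,
                        "delta_V": summary.delta_V,
                        "delta_c": summary.delta_c,
                        "combined_score": summary.combined_score,
                        "deleterious": summary.deleterious,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["failures"] = failures
    if not df.empty:
        df = df.sort_values(
            ["cohort", "tumour_id", "pair_rt", "pair_ht", "treatment"]
        ).reset_index(drop=True)
    return df


def attach_response_classes(
    df: pd.DataFrame, include_nonnegative: bool = False
) -> pd.DataFrame:
    """Add the five-class stratification per (cohort, schedule, treatment)."""
    df = df.copy()
    df["response_class"] = ""
    for _, idx in df.groupby(["cohort", "schedule", "treatment"]).groups.items():
        scores = df.loc[idx, "combined_score"].to_numpy()
        classes = stratify_cohort(scores, include_nonnegative)
        df.loc[idx, "response_class"] = [c.value for c in classes]
    return df


def _summaries_from_rows(rows: pd.DataFrame) -> dict:
    from .response_metrics import ResponseSummary

    out = {}
    for row in rows.itertuples():
        out[row.treatment] = ResponseSummary(
            delta_viable=row.delta_viable,
            delta_total=row.delta_total,
            delta_V=row.delta_V,
            delta_c=row.delta_c,
            treatment=row.treatment,
        )
    return out


def compare_from_responses(
    df: pd.DataFrame, rule2_mode: str = "better"
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the comparison rules and the two-step ranking per tumour."""
    comp_rows = []
    ranked = []
    for (cohort_name, tumour_id), tumour_df in df.groupby(
        ["cohort", "tumour_id"]
    ):
        triples = []
        for (pair_rt, pair_ht), pair_df in tumour_df.groupby(
            ["pair_rt", "pair_ht"]
        ):
            summaries = _summaries_from_rows(pair_df)
            if set(summaries) != {"R", "H", "R_H"}:
                continue  # incomplete triple (e.g. a failed integration)
            triple = MatchedTriple(
                tumour_id=int(tumour_id),
                rt=summaries["R"],
                ht=summaries["H"],
                combo=summaries["R_H"],
                schedule_pair=(pair_rt, pair_ht),
            )
            triples.append(triple)
            winner = best_treatment(triple, rule2_mode)
            comp_rows.append(
                {
                    "cohort": cohort_name,
                    "tumour_id": int(tumour_id),
                    "pair_rt": pair_rt,
                    "pair_ht": pair_ht,
                    "score_R": summaries["R"].combined_score,
                    "score_H": summaries["H"].combined_score,
                    "score_R_H": summaries["R_H"].combined_score,
                    "rule1_R": rule1_ineffective(summaries["R"]),
                    "rule1_H": rule1_ineffective(summaries["H"]),
                    "rule1_R_H": rule1_ineffective(summaries["R_H"]),
                    "winner": winner,
                }
            )
        if triples:
            outcome = rank_regimens(triples, rule2_mode)
            ranked.append(
                {
                    "cohort": cohort_name,
                    "tumour_id": outcome.tumour_id,
                    "best_treatment": outcome.best_treatment,
                    "best_regimen": outcome.best_regimen,
                    "ranking": [
                        {"treatment": t, "regimen": r, "combined_score": s}
                        for t, r, s in outcome.ranking
                    ],
                }
            )
    comp = pd.DataFrame(comp_rows)
    if not comp.empty:
        comp = comp.sort_values(
            ["cohort", "tumour_id", "pair_rt", "pair_ht"]
        ).reset_index(drop=True)
    return comp, ranked


def run_study(config: RunConfig) -> dict:
    """Run the full pipeline for one configuration; returns the manifest."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.base_params()
    options = config.solver_options()
    pairs = build_pair_grid(config.rt_grid, config.beta_grid)

    all_responses = []
    cohort_info = []
    for spec in config.cohorts:
        regime = RegimeLabel(spec["regime"])
        cohort = sample_cohort(
            regime, int(spec.get("N", 250)), int(spec.get("seed", 0)), params
        )
        write_cohort_csv(cohort, outdir / f"cohort_{regime.value}.csv")
        thresholds = {"q1_bar": q1_threshold(cohort.V0, params)}
        cohort_info.append(
            {"regime": regime.value, "N": cohort.N, "seed": cohort.seed,
             "V0": cohort.V0, **thresholds}
        )
        all_responses.append(run_sweep(cohort, pairs, options, params))

    responses = pd.concat(all_responses, ignore_index=True)
    responses = attach_response_classes(
        responses, config.include_nonnegative_percentiles
    )
    responses.to_csv(outdir / "responses.csv", index=False)

    comparison, ranked = compare_from_responses(responses, config.rule2_mode)
    comparison.to_csv(outdir / "comparison.csv", index=False)
    with open(outdir / "ranked.json", "w") as fh:
        json.dump(ranked, fh, indent=2)

    manifest = {
        "version": __version__,
        "cohorts": cohort_info,
        "rt_grid": config.rt_grid,
        "beta_grid": config.beta_grid,
        "n_schedule_pairs": len(pairs),
        "t_end": sorted({p[0].t_end for p in pairs}),
        "solver": {"method": config.method, "rtol": config.rtol,
                   "atol": config.atol},
        "flags": {
            "rule2_mode": config.rule2_mode,
            "include_nonnegative_percentiles":
                config.include_nonnegative_percentiles,
        },
        "failures": sum(
            (df.attrs.get("failures", []) for df in all_responses), []
        ),
        "runtime_s": round(time.time() - t_start, 3),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def plot_study(outdir: str | Path) -> list[Path]:
    """Figure-style summaries for a finished run (requires matplotlib).

    Writes violin plots of the combined-score distributions per cohort and
    treatment, and (q3, q1) scatter maps coloured by best treatment.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    responses = pd.read_csv(outdir / "responses.csv")
    with open(outdir / "ranked.json") as fh:
        ranked = json.load(fh)
    written = []

    cohorts_present = sorted(responses["cohort"].unique())
    fig, axes = plt.subplots(
        1, len(cohorts_present), figsize=(4 * len(cohorts_present), 4),
        squeeze=False,
    )
    for ax, name in zip(axes[0], cohorts_present):
        sub = responses[responses.cohort == name]
        data = [
            sub[sub.treatment == tr]["combined_score"].to_numpy()
            for tr in ("R", "H", "R_H")
        ]
        ax.violinplot([d for d in data if d.size], showmedians=True)
        ax.set_xticks(range(1, 1 + sum(d.size > 0 for d in data)))
        ax.set_xticklabels([t for t, d in zip(("R", "H", "R_H"), data)
                            if d.size])
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_title(f"{name} cohort")
        ax.set_ylabel("combined score (pp)")
    fig.tight_layout()
    path = outdir / "score_distributions.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    best = {(r["cohort"], r["tumour_id"]): r["best_treatment"] for r in ranked}
    colours = {"R": "tab:orange", "H": "tab:red", "R_H": "tab:purple",
               "none_effective": "0.6"}
    fig, axes = plt.subplots(
        1, len(cohorts_present), figsize=(4 * len(cohorts_present), 4),
        squeeze=False,
    )
    for ax, name in zip(axes[0], cohorts_present):
        sub = responses[responses.cohort == name].drop_duplicates("tumour_id")
        labels = [best.get((name, tid), "none_effective")
                  for tid in sub["tumour_id"]]
        ax.scatter(sub["q3"], sub["q1"],
                   c=[colours[l] for l in labels], s=14)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("q3")
        ax.set_ylabel("q1")
        ax.set_title(f"{name}: best treatment")
    fig.tight_layout()
    path = outdir / "best_treatment_map.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.group()
@click.version_option(__version__)
def main() -> None:
    """Virtual-trial pipeline for tumour responses to RT, HT and RT+HT."""


@main.command()
@click.option("--v0", type=float, required=True, help="Vascular volume V(0).")
@click.option("--q1", type=float, default=None,
              help="If given, also print the q3 threshold at this q1.")
def thresholds(v0: float, q1: float | None) -> None:
    """Print the sampling thresholds for a given vascular volume."""
    q1_bar = q1_threshold(v0)
    click.echo(f"q1_bar({v0}) = {q1_bar:.6f}")
    if q1 is not None:
        try:
            click.echo(f"q3_bar({v0}, q1={q1}) = {q3_threshold(v0, q1):.6f}")
        except (NoRootError, ValueError) as exc:
            click.echo(f"q3_bar undefined: {exc}")


@main.command()
@click.option("--regime", type=click.Choice(["NL", "SL", "BS"]), required=True)
@click.option("-n", "--size", type=int, default=250, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def cohort(regime: str, size: int, seed: int, out: str) -> None:
    """Sample a virtual cohort and write it as CSV."""
    c = sample_cohort(RegimeLabel(regime), size, seed)
    write_cohort_csv(c, out)
    click.echo(f"wrote {size} {regime} tumours to {out}")


def _schedule_from_options(modality, d, n_frac, beta, n_wks) -> Schedule:
    if modality == "RT":
        return build_rt_schedule(d, n_frac)
    if modality == "HT":
        return build_ht_schedule(beta, n_wks)
    return build_combined(d, n_frac, beta)


@main.command("simulate")
@click.option("--q1", type=float, required=True)
@click.option("--q3", type=float, required=True)
@click.option("--v0", type=float, required=True)
@click.option("--modality", type=click.Choice(["RT", "HT", "RT_HT"]),
              default="RT", show_default=True)
@click.option("-d", "--dose", type=float, default=2.0, show_default=True)
@click.option("--n-frac", type=int, default=5, show_default=True)
@click.option("--beta", type=float, default=0.005, show_default=True)
@click.option("--n-wks", type=int, default=8, show_default=True,
              help="HT-only treatment duration (RT plans set their own).")
@click.option("--rtol", type=float, default=1e-8, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate_cmd(q1, q3, v0, modality, dose, n_frac, beta, n_wks, rtol, out):
    """Simulate one tumour under one schedule and write the trajectory CSV."""
    regime = classify_regime(q1, q3, v0)
    fp = (
        sl_fixed_point(q1, q3, v0)
        if regime is RegimeLabel.SL
        else nl_fixed_point(q1, q3, v0)
    )
    tumour = VirtualTumour(id=0, q1=q1, q3=q3, V0=v0, regime=regime,
                           T_star=fp.T_star, c_star=fp.c_star)
    schedule = _schedule_from_options(modality, dose, n_frac, beta, n_wks)
    traj = simulate(tumour, schedule, SolverOptions(rtol=rtol))
    traj.to_frame().to_csv(out, index=False)
    means = last_week_means(traj, schedule)
    summary = percent_changes(means, tumour)
    click.echo(
        f"{regime.value} tumour under {schedule.describe()}: "
        f"dViable={summary.delta_viable:.2f}% dTotal={summary.delta_total:.2f}% "
        f"dV={summary.delta_V:.2f}% dC={summary.delta_c:.2f}%"
    )


@main.command()
@click.option("--cohort-csv", type=click.Path(exists=True), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML with rt_grid / beta_grid / solver.")
@click.option("--out", type=click.Path(), required=True)
def sweep(cohort_csv: str, config_path: str | None, out: str) -> None:
    """Simulate a schedule grid over an existing cohort CSV."""
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    c = read_cohort_csv(cohort_csv)
    pairs = build_pair_grid(config.rt_grid, config.beta_grid)
    df = run_sweep(c, pairs, config.solver_options(), config.base_params())
    df = attach_response_classes(df, config.include_nonnegative_percentiles)
    df.to_csv(out, index=False)
    click.echo(f"wrote {len(df)} response rows to {out}")


@main.command()
@click.option("--responses", type=click.Path(exists=True), required=True)
@click.option("--rule2-mode", type=click.Choice(["better", "both"]),
              default="better", show_default=True)
@click.option("--out-comparison", type=click.Path(), required=True)
@click.option("--out-ranked", type=click.Path(), required=True)
def compare(responses, rule2_mode, out_comparison, out_ranked) -> None:
    """Apply the comparison rules to an existing responses CSV."""
    df = pd.read_csv(responses)
    comp, ranked = compare_from_responses(df, rule2_mode)
    comp.to_csv(out_comparison, index=False)
    with open(out_ranked, "w") as fh:
        json.dump(ranked, fh, indent=2)
    click.echo(
        f"wrote {len(comp)} comparisons to {out_comparison} and "
        f"{len(ranked)} ranked outcomes to {out_ranked}"
    )


@main.command()
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None)
@click.option("--outdir", type=click.Path(), default=None,
              help="Override the configured output directory.")
@click.option("--plots", is_flag=True, default=False,
              help="Also write summary figures (requires matplotlib).")
def study(config_path: str | None, outdir: str | None, plots: bool) -> None:
    """Run the full pipeline (cohorts, sweep, comparison, manifest)."""
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    if outdir is not None:
        config.outdir = outdir
    manifest = run_study(config)
    if plots:
        for path in plot_study(config.outdir):
            click.echo(f"wrote {path}")
    click.echo(json.dumps(manifest, indent=2))


if __name__ == "__main__":
    main()
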