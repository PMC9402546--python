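"""End-to-end pipeline: simulate -> fit -> regime -> stats -> report.

Each stage reads and writes plain CSV/JSON in an output directory, so a run
can resume from any cached intermediate (pass ``force=True`` to recompute).
All randomness derives from one master seed recorded in the report header.

The ``reproduce`` entry point runs the regime fit and the AQ normality test
on a user-supplied copy of a deposited dataset, adapting to its layout via a
column-mapping config; nothing is ever downloaded implicitly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    EXP2_BIAS_PROFILE,
    CohortSpec,
    generate_cohort,
    simulate_control,
    simulate_experiment,
)
from .designs import DESIGNS, regime_of
from .inferstats import (
    jarque_bera,
    log10_bf_correlation,
    one_sample_t,
    pearson_correlation,
    posthoc_bonferroni,
    rm_anova2,
)
from .observer import ObserverParams
from .psychofit import TRIAL_COLUMNS, fit_all_cells
from .regimefit import fit_two_limb, group_mean_wf

log = logging.getLogger("numerosym")

REQUIRED_TRIAL_COLUMNS = TRIAL_COLUMNS


class SchemaError(ValueError):
    """Malformed config or CSV; the message names the offending field."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"config {path} did not parse to a mapping")
    return cfg


def _parse_bias_profile(raw: dict) -> dict:
    """Config bias profile: {'condition:selector': [mean, sd]}, selector a
    regime name or an integer standard numerosity."""
    profile = {}
    for key, val in raw.items():
        cond, _, sel = str(key).partition(":")
        selector = int(sel) if sel.isdigit() else sel
        if selector not in ("estimation", "density") and not isinstance(selector, int):
            raise SchemaError(f"bias_profile key {key!r}: bad selector {sel!r}")
        mean, sd = val
        profile[(cond, selector)] = (float(mean), float(sd))
    return profile


def spec_from_config(cfg: dict, seed: int | None = None) -> tuple[CohortSpec, str]:
    experiment = cfg.get("experiment", "exp1")
    if experiment not in DESIGNS:
        raise SchemaError(f"experiment: unknown design {experiment!r}")
    kwargs = {}
    for field_name in (
        "n_participants", "wf0_mean", "wf0_sd", "n_switch_mean", "n_switch_sd",
        "alpha_mean", "alpha_sd", "aq_mean", "aq_sd", "aq_bias_correlation",
    ):
        if field_name in cfg:
            kwargs[field_name] = cfg[field_name]
    if "bias_profile" in cfg:
        kwargs["bias_profile"] = _parse_bias_profile(cfg["bias_profile"])
    elif experiment == "exp2":
        kwargs["bias_profile"] = dict(EXP2_BIAS_PROFILE)
    kwargs["master_seed"] = seed if seed is not None else cfg.get("seed", 0)
    return CohortSpec(**kwargs), experiment


def validate_trials(df: pd.DataFrame, source: str = "trials") -> pd.DataFrame:
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required columns {missing}")
    if (df["n_test"] < 1).any():
        raise SchemaError(f"{source}: column n_test contains values < 1")
    if not df["session"].isin([1, 2]).all():
        raise SchemaError(f"{source}: column session must be 1 or 2")
    return df


def _simulate_aq_table(cohort: list[ObserverParams]) -> pd.DataFrame:
    return pd.DataFrame(
        {"participant_id": [p.participant_id for p in cohort],
         "aq_total": [p.aq_score for p in cohort]}
    )


def stage_simulate(out: Path, cfg: dict, seed: int, force: bool = False) -> Path:
    trials_path = out / "trials.csv"
    if trials_path.exists() and not force:
        log.info("simulate: using cached %s", trials_path)
        return trials_path
    spec, experiment = spec_from_config(cfg, seed)
    design = DESIGNS[experiment]
    cohort = generate_cohort(spec, standards=tuple(sorted(set(design.standards))))
    trials = simulate_experiment(
        cohort, design, master_seed=spec.master_seed, quest_kwargs=cfg.get("quest")
    )
    trials.to_csv(trials_path, index=False)
    _simulate_aq_table(cohort).to_csv(out / "aq_scores.csv", index=False)
    (out / "observers.json").write_text(
        json.dumps([p.to_dict() for p in cohort], indent=1)
    )
    log.info("simulate: %d trials, %d participants", len(trials), len(cohort))
    return trials_path


def stage_fit(out: Path, force: bool = False) -> Path:
    fits_path = out / "fits.csv"
    if fits_path.exists() and not force:
        log.info("fit: using cached %s", fits_path)
        return fits_path
    trials = validate_trials(pd.read_csv(out / "trials.csv"), "trials.csv")
    fits = fit_all_cells(trials)
    n_bad = int((~fits["converged"]).sum())
    if n_bad:
        log.warning("fit: %d non-converged cells excluded downstream", n_bad)
    fits.to_csv(fits_path, index=False)
    return fits_path


def stage_regime(out: Path, force: bool = False) -> Path:
    regime_path = out / "regime.csv"
    if regime_path.exists() and not force:
        return regime_path
    fits = pd.read_csv(out / "fits.csv")
    rows = []
    for cond, sub in fits.groupby("condition"):
        n_vals, wf_vals = group_mean_wf(sub)
        if len(n_vals) >= 4:
            fit = fit_two_limb(n_vals, wf_vals)
            rows.append(
                {"condition": cond, "wf0": fit.wf0, "n_switch": fit.n_switch,
                 "alpha": fit.alpha, "rss": fit.rss, "n_points": fit.n_points}
            )
    cols = ["condition", "wf0", "n_switch", "alpha", "rss", "n_points"]
    pd.DataFrame(rows, columns=cols).to_csv(regime_path, index=False)
    return regime_path


def _bias_summary(fits: pd.DataFrame) -> pd.DataFrame:
    ok = fits[fits["converged"]].copy()
    ok["regime"] = [regime_of(n) for n in ok["n_standard"]]
    return (
        ok.groupby(["condition", "regime"])["bias_percent"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )


def symmetry_bias_by_participant(
    fits: pd.DataFrame, condition: str = "vertical", regime: str = "estimation"
) -> pd.Series:
    """Per-participant symmetry bias averaged over one regime's standards."""
    ok = fits[fits["converged"] & (fits["condition"] == condition)].copy()
    ok["regime"] = [regime_of(n) for n in ok["n_standard"]]
    return ok[ok["regime"] == regime].groupby("participant_id")["bias_percent"].mean()


def stage_stats(out: Path, force: bool = False) -> Path:
    stats_path = out / "stats.json"
    if stats_path.exists() and not force:
        return stats_path
    fits = pd.read_csv(out / "fits.csv")
    ok = fits[fits["converged"]]
    report: dict = {"n_nonconverged": int((~fits["converged"]).sum())}

    report["bias_summary"] = _bias_summary(fits).to_dict(orient="records")

    complete = (
        ok.groupby(["participant_id"])
        .filter(lambda g: len(g) == ok.groupby("participant_id").size().max())
    )
    long = complete.rename(columns={"wf": "value"})
    try:
        report["anova_wf"] = {
            k: v.__dict__ for k, v in rm_anova2(long, dv="value").effects.items()
        }
        long_b = complete.rename(columns={"bias_percent": "value"})
        report["anova_bias"] = {
            k: v.__dict__ for k, v in rm_anova2(long_b, dv="value").effects.items()
        }
    except ValueError as e:  # non-converged holes can unbalance the design
        report["anova_error"] = str(e)

    # per-N one-sample t-tests of the symmetric-condition bias against 0,
    # Bonferroni-corrected over the tested numerosities
    sym = ok[ok["condition"].isin(["vertical", "double"])]
    pairs = []
    for (cond, n_std), cell in sym.groupby(["condition", "n_standard"]):
        x = cell["bias_percent"].to_numpy()
        if len(x) >= 2:
            pairs.append((f"{cond}_N{n_std}", x, np.zeros_like(x)))
    if pairs:
        report["bias_ttests"] = posthoc_bonferroni(pairs).to_dict(orient="records")

    aq_path = out / "aq_scores.csv"
    if aq_path.exists():
        aq = pd.read_csv(aq_path).set_index("participant_id")["aq_total"]
        for regime in ("estimation", "density"):
            bias = symmetry_bias_by_participant(fits, regime=regime)
            joined = pd.concat([bias, aq], axis=1, join="inner").dropna()
            if len(joined) >= 4:
                r, p = pearson_correlation(joined["bias_percent"], joined["aq_total"])
                report[f"aq_correlation_{regime}"] = {
                    "r": r, "p": p, "n": len(joined),
                    "log10_bf": log10_bf_correlation(r, len(joined)),
                }
        if len(aq) >= 3 and aq.std() > 0:
            jb, p = jarque_bera(aq.to_numpy())
            report["aq_jarque_bera"] = {"JB": jb, "p": p, "n": len(aq)}

    control_path = out / "control.csv"
    if control_path.exists():
        control = pd.read_csv(control_path)
        report["control_ttests"] = [
            {"n_standard": int(n),
             "mean_accuracy": float(g["accuracy"].mean()),
             **dict(zip(("t", "p", "cohen_d"), one_sample_t(g["accuracy"], 0.5)))}
            for n, g in control.groupby("n_standard")
        ]

    stats_path.write_text(json.dumps(report, indent=1, default=float))
    return stats_path


def stage_report(out: Path, seed: int, force: bool = False) -> Path:
    report_path = out / "report.txt"
    if report_path.exists() and not force:
        return report_path
    stats = json.loads((out / "stats.json").read_text())
    regime = pd.read_csv(out / "regime.csv")
    lines = [
        f"numerosym {__version__} pipeline report",
        f"master seed: {seed}",
        f"non-converged fits excluded: {stats.get('n_nonconverged', 0)}",
        "",
        "Two-limb Weber curve per condition:",
        regime.to_string(index=False)
        if len(regime)
        else "(needs >= 4 standard numerosities per condition)",
        "",
        "Group bias (percent) by condition x regime:",
        pd.DataFrame(stats["bias_summary"]).to_string(index=False),
    ]
    for regime_name in ("estimation", "density"):
        key = f"aq_correlation_{regime_name}"
        if key in stats:
            c = stats[key]
            lines.append(
                f"\nAQ vs symmetry bias ({regime_name}): r = {c['r']:.2f}, "
                f"p = {c['p']:.3f}, LBF = {c['log10_bf']:.2f} (n = {c['n']})"
            )
    report_path.write_text("\n".join(lines) + "\n")
    return report_path


def run_pipeline(
    config: dict | str | Path, out_dir: str | Path, seed: int = 0, force: bool = False
) -> Path:
    """Run every stage; returns the report path."""
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(out, cfg, seed, force)
    stage_fit(out, force)
    stage_regime(out, force)
    stage_stats(out, force)
    return stage_report(out, seed, force)


DEFAULT_ZENODO_MAPPING = {
    "wf_file": "weber_fractions.csv",
    "wf_columns": {"n": "n_standard", "wf": "wf", "condition": "condition"},
    "aq_file": "aq_scores.csv",
    "aq_column": "aq_total",
}


def reproduce_from_deposit(deposit_dir: str | Path, mapping: dict | None = None) -> dict:
    """Regime fits and AQ normality test on a local copy of the deposited data.

    ``mapping`` adapts to the deposit's file and column names (defaults in
    :data:`DEFAULT_ZENODO_MAPPING`).  The directory must already exist
    locally; this function performs no network access.
    """
    deposit = Path(deposit_dir)
    m = {**DEFAULT_ZENODO_MAPPING, **(mapping or {})}
    out: dict = {}
    wf_path = deposit / m["wf_file"]
    if wf_path.exists():
        cols = m["wf_columns"]
        df = pd.read_csv(wf_path)
        for role, name in cols.items():
            if name not in df.columns:
                raise SchemaError(f"{wf_path.name}: missing column {name!r} for {role!r}")
        out["regime_fits"] = {}
        for cond, sub in df.groupby(cols["condition"]):
            g = sub.groupby(cols["n"])[cols["wf"]].mean()
            fit = fit_two_limb(g.index.to_numpy(float), g.to_numpy())
            out["regime_fits"][str(cond)] = {
                "wf0": fit.wf0, "n_switch": fit.n_switch, "alpha": fit.alpha,
            }
    aq_path = deposit / m["aq_file"]
    if aq_path.exists():
        aq = pd.read_csv(aq_path)
        col = m["aq_column"]
        if col not in aq.columns:
            raise SchemaError(f"{aq_path.name}: missing column {col!r}")
        jb, p = jarque_bera(aq[col].to_numpy(float))
        out["aq_jarque_bera"] = {"JB": jb, "p": p, "n": int(len(aq))}
    if not out:
        raise SchemaError(
            f"no recognised files in {deposit} (expected {m['wf_file']} or {m['aq_file']})"
        )
    return out
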