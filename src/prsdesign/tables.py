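"""Scenario reports and reproduction of the published result tables.

Everything here is orchestration: the analytic chain lives in
``polygenic_moments`` / ``combined_score`` / ``discrimination`` /
``reclassification``; this module turns parameter sets into tidy tables and
compares them with the bundled published reference values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace
from pathlib import Path

import pandas as pd
import yaml

from . import discrimination, reclassification
from ._published import REFERENCE
from .combined_score import combine
from .design import evaluate_objective, optimize_threshold
from .model import (
    EnvModel,
    PolygenicDesign,
    Scenario,
    TraitModel,
    make_scenario,
)
from .polygenic_moments import score_moments, selection_quantiles

logger = logging.getLogger("prsdesign")

__all__ = ["load_config", "run_scenario", "reproduce_tables", "TABLE_IDS"]

OUTPUT_COLUMNS = ["scenario", "scheme", "rho", "p1", "n", "metric", "value"]

# Supplementary variants: same computation as a main table under an altered
# prevalence or null-marker proportion.
_SUPPLEMENTARY = {
    "S1": ("2", {"K": 0.06}),
    "S2": ("2", {"pi0": 0.95}),
    "S3": ("3", {"K": 0.06}),
    "S4": ("3", {"pi0": 0.95}),
    "S5": ("4", {"K": 0.06}),
    "S6": ("4", {"pi0": 0.95}),
    "S7": ("5", {"K": 0.1}),
    "S8": ("5", {"pi0": 0.8}),
    "S9": ("6", {"K": 0.1}),
    "S10": ("6", {"pi0": 0.8}),
    "S11": ("7", {"K": 0.1}),
    "S12": ("7", {"pi0": 0.8}),
}
TABLE_IDS = tuple("234567") + tuple(_SUPPLEMENTARY)


def _build_section(cls, section: dict, name: str):
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [{name}] config section: {exc}") from exc


def load_config(source) -> tuple[list[Scenario], dict]:
    """Parse a YAML config (path, YAML text, or dict) into scenarios + metric settings.

    A config either names a preset (``scenario: cvd`` with optional ``rho``,
    ``r2_gx``, ``K``, ``pi0``, ``p1`` overrides), spells out ``design`` /
    ``trait`` / ``env`` sections field by field, or carries a ``scenarios``
    list of such mappings.  ``metrics`` holds ``schemes``,
    ``risk_thresholds``, ``quantiles`` and ``p1`` values.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        cfg = yaml.safe_load(Path(source).read_text())
    elif isinstance(source, str):
        cfg = yaml.safe_load(source)
    else:
        cfg = dict(source)
    if cfg is None:
        cfg = {}

    entries = cfg.get("scenarios")
    if entries is None:
        entries = [cfg] if ("scenario" in cfg or "design" in cfg) else []

    scenarios = []
    for entry in entries:
        if "scenario" in entry:
            keys = {k: entry[k] for k in ("rho", "r2_gx", "K", "pi0", "p1") if k in entry}
            scenarios.append(make_scenario(entry["scenario"], **keys))
        else:
            design = _build_section(PolygenicDesign, entry["design"], "design")
            trait = _build_section(TraitModel, entry["trait"], "trait")
            env = _build_section(EnvModel, entry.get("env", {"r2_xy": 0.0}), "env")
            name = entry.get("name", "custom")
            scenarios.append(Scenario(name, design, trait, env))
    metrics = cfg.get("metrics", {})
    return scenarios, metrics


def _metric_rows(scenario: Scenario, scheme: str, p1: float | None = None) -> list[dict]:
    """All analytic metrics of one scenario/scheme at one selection threshold."""
    design = scenario.design if p1 is None else replace(scenario.design, p1=p1)
    trait, env = scenario.trait, scenario.env
    moments = score_moments(design, trait, env)
    comb = combine(moments, env, scheme)
    base = {
        "scenario": scenario.name,
        "scheme": scheme,
        "rho": env.rho,
        "p1": design.p1,
        "n": design.n,
    }
    quant = selection_quantiles(design, trait)
    logger.info(
        "%s/%s p1=%g: theta=%.4f cov_sy=%.5g var_s=%.5g cov_sx=%.5g "
        "w=(%.4f, %.4f) gamma=%.4f r2_comb=%.5g",
        scenario.name, scheme, design.p1, quant.theta,
        moments.cov_sy, moments.var_s, moments.cov_sx,
        comb.w1, comb.w2, comb.gamma, comb.r2_comb,
    )
    if trait.is_binary:
        logger.info("%s: tau=%.4f c=%.4f", scenario.name, trait.tau, trait.c)

    rows = [dict(base, metric="r2", value=comb.r2_comb)]
    if not trait.is_binary:
        return rows
    K = trait.K
    rows.append(dict(base, metric="auc", value=discrimination.auc(comb.r2_comb, K)))
    for q in (0.1, 0.2, 0.5):
        rows.append(
            dict(base, metric=f"capture_q{q}", value=discrimination.case_capture(comb.r2_comb, K, q))
        )
    joint = reclassification.TrivariateJoint.from_scores(comb, env)
    cnri = reclassification.continuous_nri(joint, K)
    rows.append(dict(base, metric="cnri_case", value=cnri[0]))
    rows.append(dict(base, metric="cnri_control", value=cnri[1]))
    rows.append(dict(base, metric="idi", value=reclassification.idi(comb, env, K)))
    return rows


def run_scenario(config, out: str | Path | None = None) -> pd.DataFrame:
    """Tidy metric table for every scenario/scheme/threshold in the config.

    Writes TSV to ``out`` when given; intermediate derived quantities
    (threshold tau, scale factor c, selection quantiles, score moments,
    weights, calibration) are logged at INFO level.
    """
    scenarios, metrics = load_config(config)
    schemes = metrics.get("schemes", ["polygenic", "environment", "unweighted", "ols"])
    p1_values = metrics.get("p1", None)
    rows: list[dict] = []
    for scenario in scenarios:
        for scheme in schemes:
            for p1 in p1_values or [None]:
                rows.extend(_metric_rows(scenario, scheme, p1))
    frame = pd.DataFrame(rows, columns=OUTPUT_COLUMNS)
    if out is not None:
        frame.to_csv(out, sep="\t", index=False)
    return frame


# --- published table layouts -------------------------------------------------

_GW = 5e-8


def _auc_cell(scenario: Scenario, scheme: str, p1: float | None, n: float, optimal: bool):
    design = replace(scenario.design, n=n)
    if optimal and not math.isinf(n):
        _, value = optimize_threshold(design, scenario.trait, scenario.env, scheme, "auc")
        return value
    design = replace(design, p1=1.0 if math.isinf(n) else p1)
    return evaluate_objective(design, scenario.trait, scenario.env, scheme, "auc")


def _rows_spec(n_train: float):
    return [("genome-wide", n_train, False), ("optimal", n_train, True), ("infinite", math.inf, False)]


def _table_2_or_5(scenario_name: str, overrides: dict) -> pd.DataFrame:
    scn = make_scenario(scenario_name, **overrides)
    if scenario_name == "cvd":
        columns = [
            ("poly", "polygenic", {}),
            ("unweighted_rho0.1", "unweighted", {"rho": 0.1}),
            ("unweighted_rho0.4", "unweighted", {"rho": 0.4}),
            ("ols_rho0.1", "ols", {"rho": 0.1}),
            ("ols_rho0.4", "ols", {"rho": 0.4}),
        ]
    else:
        columns = [
            ("poly", "polygenic", {}),
            ("ols_gx0.1_rho0.1", "ols", {"r2_gx": 0.1, "rho": 0.1}),
            ("ols_gx0.1_rho0.4", "ols", {"r2_gx": 0.1, "rho": 0.4}),
            ("ols_gx0.8_rho0.1", "ols", {"r2_gx": 0.8, "rho": 0.1}),
            ("ols_gx0.8_rho0.4", "ols", {"r2_gx": 0.8, "rho": 0.4}),
        ]
    rows = []
    for row_label, n, optimal in _rows_spec(scn.design.n):
        rows.append(
            {
                "row": row_label,
                "env": discrimination.auc(scn.env.r2_xy, scn.trait.K),
                **{
                    label: _auc_cell(scn.with_(**env_kw), scheme, _GW, n, optimal)
                    for label, scheme, env_kw in columns
                },
            }
        )
    return pd.DataFrame(rows).set_index("row")


def _reclass_cells(scn: Scenario, scheme: str, a: float, n: float, optimal: bool) -> dict:
    design = replace(scn.design, n=n)
    out = {}
    specs = [
        ("nri_case", "nri_case", a),
        ("nri_control", "nri_control", a),
        ("cnri_case", "cnri", None),
        ("cnri_control", "cnri", None),  # threshold optimized for the case component
        ("idi", "idi", None),
    ]
    for label, objective, thr in specs:
        if optimal and not math.isinf(n):
            p1, _ = optimize_threshold(design, scn.trait, scn.env, scheme, objective, thr)
        else:
            p1 = 1.0 if math.isinf(n) else design.p1
        d = replace(design, p1=p1)
        moments = score_moments(d, scn.trait, scn.env)
        comb = combine(moments, scn.env, scheme)
        joint = reclassification.TrivariateJoint.from_scores(comb, scn.env)
        if label.startswith("nri_"):
            case, control = reclassification.categorical_nri(joint, a, scn.trait.K)
            out[label] = case if label == "nri_case" else control
        elif label.startswith("cnri_"):
            case, control = reclassification.continuous_nri(joint, scn.trait.K)
            out[label] = case if label == "cnri_case" else control
        else:
            out[label] = reclassification.idi(comb, scn.env, scn.trait.K)
    return out


def _table_3(overrides: dict) -> pd.DataFrame:
    rows = []
    for row_label, n, optimal in _rows_spec(make_scenario("cvd").design.n):
        row = {"row": row_label}
        for scheme in ("unweighted", "ols"):
            for rho in (0.1, 0.4):
                scn = make_scenario("cvd", rho=rho, **overrides)
                cells = _reclass_cells(scn, scheme, 0.10, n, optimal)
                row[f"nri_case_{scheme}_rho{rho}"] = cells["nri_case"]
                row[f"nri_control_{scheme}_rho{rho}"] = cells["nri_control"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("row")


def _table_4_or_6(scenario_name: str, a: float, overrides: dict) -> pd.DataFrame:
    kw = {"rho": 0.4} if scenario_name == "cvd" else {"rho": 0.4, "r2_gx": 0.8}
    scn = make_scenario(scenario_name, **kw, **overrides)
    rows = []
    for row_label, n, optimal in _rows_spec(scn.design.n):
        rows.append({"row": row_label, **_reclass_cells(scn, "ols", a, n, optimal)})
    return pd.DataFrame(rows).set_index("row")


def _table_7(overrides: dict) -> pd.DataFrame:
    scn = make_scenario("breast_cancer", rho=0.4, r2_gx=0.8, **overrides)
    K = scn.trait.K
    rows = []
    for row_label, n, optimal in _rows_spec(scn.design.n):
        design = replace(scn.design, n=n)
        if optimal:
            p1_poly, _ = optimize_threshold(design, scn.trait, scn.env, "polygenic", "auc")
            p1_comb, _ = optimize_threshold(design, scn.trait, scn.env, "ols", "auc")
        else:
            p1_poly = p1_comb = 1.0 if math.isinf(n) else _GW
        row = {"row": row_label}
        for q in (0.1, 0.2, 0.5):
            poly = combine(
                score_moments(replace(design, p1=p1_poly), scn.trait, scn.env), scn.env, "polygenic"
            )
            comb = combine(
                score_moments(replace(design, p1=p1_comb), scn.trait, scn.env), scn.env, "ols"
            )
            row[f"capture_q{q}_poly"] = discrimination.case_capture(poly.r2_comb, K, q)
            row[f"capture_q{q}_env"] = discrimination.case_capture(scn.env.r2_xy, K, q)
            row[f"capture_q{q}_comb"] = discrimination.case_capture(comb.r2_comb, K, q)
        rows.append(row)
    return pd.DataFrame(rows).set_index("row")


def _compute_table(base: str, overrides: dict) -> pd.DataFrame:
    if base == "2":
        return _table_2_or_5("cvd", overrides)
    if base == "3":
        return _table_3(overrides)
    if base == "4":
        return _table_4_or_6("cvd", 0.20, overrides)
    if base == "5":
        return _table_2_or_5("breast_cancer", overrides)
    if base == "6":
        return _table_4_or_6("breast_cancer", 0.08, overrides)
    if base == "7":
        return _table_7(overrides)
    raise ValueError(f"unknown table id {base!r}")


def reproduce_tables(which, outdir: str | Path, precision: int | None = None) -> list[Path]:
    """Recompute published tables (2-7 and supplementary variants S1-S12).

    Writes one TSV per table to ``outdir``; for the main tables a
    ``table<k>_diff.tsv`` compares each cell against the bundled published
    values.  ``which`` is a table id or iterable of ids.  Returns the paths
    written.
    """
    if isinstance(which, (str, int)):
        which = [which]
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for table_id in [str(w).upper() if str(w).startswith(("s", "S")) else str(w) for w in which]:
        if table_id not in TABLE_IDS:
            raise ValueError(f"unknown table id {table_id!r}; expected one of {TABLE_IDS}")
        base, overrides = _SUPPLEMENTARY.get(table_id, (table_id, {}))
        frame = _compute_table(base, overrides)
        if precision is not None:
            frame = frame.round(precision)
        path = outdir / f"table{table_id}.tsv"
        frame.to_csv(path, sep="\t")
        written.append(path)
        reference = REFERENCE.get(table_id)
        if reference:
            diff_rows = [
                {
                    "row": row,
                    "column": col,
                    "published": ref,
                    "computed": frame.loc[row, col],
                    "difference": frame.loc[row, col] - ref,
                }
                for (row, col), ref in reference.items()
            ]
            diff_path = outdir / f"table{table_id}_diff.tsv"
            pd.DataFrame(diff_rows).to_csv(diff_path, sep="\t", index=False)
            written.append(diff_path)
    return written
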