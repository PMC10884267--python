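"""CSV dialects, run configuration, and the end-to-end pipeline.

Input tables
------------
Study CSV (one row per study x pair):
    study_id, cond_a, cond_b, n11, n10, n01, n00, log_or, se_log_or,
    prev_a, prev_b — either the four count columns or the two effect
    columns are filled, never both.
Prevalence CSV: condition, prev, ci_low, ci_high (percent or proportion;
    declared by a units flag, stored internally as proportions).
Fixed-OR CSV: cond_a, cond_b, odds_ratio, se_log_or — externally pooled
    ORs for pairs with no local evidence.

``run_pipeline`` chains synthesis -> joint model -> bootstrap ->
comorbidity summaries and writes the report CSVs (square matrices of theta,
joint prevalence and conditional prevalence, a comorbidity table) plus a
machine-readable run manifest.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .bootstrap import (
    BootstrapConfig,
    ComorbidityBootstrap,
    PairBootstrap,
    bootstrap_comorbidity,
    bootstrap_pair,
)
from .contingency import ContingencyTable, StudyRecord
from .joint import (
    ComorbidityProfile,
    PairPrevalence,
    PrevalenceEstimate,
    comorbidity_profile,
    fit_comorbidity_regression,
    pair_prevalence,
)
from .synthesis import PairAssociation, select_synthesis

log = logging.getLogger("comorbid")

_COUNT_COLS = ["n11", "n10", "n01", "n00"]
_EFFECT_COLS = ["log_or", "se_log_or"]


class InputError(ValueError):
    """Malformed or inconsistent input tables."""


def _read_table(path: Path | str) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    return pd.read_csv(path)


def read_study_csv(path: Path | str) -> list[StudyRecord]:
    """Read study records, validating the exclusive-evidence rule row by row."""
    df = _read_table(path)
    required = {"study_id", "cond_a", "cond_b"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        has_counts = all(c in df.columns and pd.notna(row[c]) for c in _COUNT_COLS)
        any_counts = any(c in df.columns and pd.notna(row[c]) for c in _COUNT_COLS)
        has_effect = all(c in df.columns and pd.notna(row[c]) for c in _EFFECT_COLS)
        any_effect = any(c in df.columns and pd.notna(row[c]) for c in _EFFECT_COLS)
        if any_counts and any_effect:
            errors.append(f"line {line}: both count and effect columns filled")
            continue
        if not has_counts and not has_effect:
            errors.append(f"line {line}: neither complete counts nor complete effect")
            continue
        try:
            if has_counts:
                rec = StudyRecord(
                    study_id=str(row["study_id"]),
                    cond_a=str(row["cond_a"]),
                    cond_b=str(row["cond_b"]),
                    table=ContingencyTable(*(int(row[c]) for c in _COUNT_COLS)),
                )
            else:
                rec = StudyRecord(
                    study_id=str(row["study_id"]),
                    cond_a=str(row["cond_a"]),
                    cond_b=str(row["cond_b"]),
                    log_or=float(row["log_or"]),
                    se_log_or=float(row["se_log_or"]),
                    prev_a=float(row["prev_a"]) if pd.notna(row.get("prev_a")) else None,
                    prev_b=float(row["prev_b"]) if pd.notna(row.get("prev_b")) else None,
                )
            records.append(rec)
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise InputError(f"{path}: " + "; ".join(errors))
    return records


def write_study_csv(records: Sequence[StudyRecord], path: Path | str) -> None:
    rows = []
    for r in records:
        row = {
            "study_id": r.study_id,
            "cond_a": r.cond_a,
            "cond_b": r.cond_b,
            "n11": r.table.n11 if r.table else None,
            "n10": r.table.n10 if r.table else None,
            "n01": r.table.n01 if r.table else None,
            "n00": r.table.n00 if r.table else None,
            "log_or": r.log_or,
            "se_log_or": r.se_log_or,
            "prev_a": None if r.table else r.prev_a,
            "prev_b": None if r.table else r.prev_b,
        }
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prevalence_csv(
    path: Path | str, units: str = "percent"
) -> list[PrevalenceEstimate]:
    """Read the marginal prevalence table; percent inputs are converted once."""
    df = _read_table(path)
    missing = {"condition", "prev", "ci_low", "ci_high"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    if units not in ("percent", "proportion"):
        raise InputError("units must be 'percent' or 'proportion'")
    scale = 0.01 if units == "percent" else 1.0
    out, errors = [], []
    for idx, row in df.iterrows():
        try:
            out.append(
                PrevalenceEstimate(
                    condition=str(row["condition"]),
                    prev=float(row["prev"]) * scale,
                    ci_low=float(row["ci_low"]) * scale,
                    ci_high=float(row["ci_high"]) * scale,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {idx + 2}: {exc}")
    if errors:
        raise InputError(f"{path}: " + "; ".join(errors))
    return out


def write_prevalence_csv(
    prevalences: Sequence[PrevalenceEstimate], path: Path | str, units: str = "percent"
) -> None:
    scale = 100.0 if units == "percent" else 1.0
    pd.DataFrame(
        {
            "condition": [p.condition for p in prevalences],
            "prev": [p.prev * scale for p in prevalences],
            "ci_low": [p.ci_low * scale for p in prevalences],
            "ci_high": [p.ci_high * scale for p in prevalences],
        }
    ).to_csv(path, index=False)


def read_fixed_or_csv(path: Path | str) -> dict[tuple[str, str], tuple[float, float]]:
    """Externally pooled ORs keyed by sorted condition pair -> (OR, se_log_or)."""
    df = _read_table(path)
    missing = {"cond_a", "cond_b", "odds_ratio", "se_log_or"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        key = tuple(sorted((str(row["cond_a"]), str(row["cond_b"]))))
        out[key] = (float(row["odds_ratio"]), float(row["se_log_or"]))
    return out


def write_association_csv(assocs: Sequence[PairAssociation], path: Path | str) -> None:
    rows = []
    for a in assocs:
        rows.append(
            {
                "cond_a": a.cond_a,
                "cond_b": a.cond_b,
                "mode": a.mode,
                "k_studies": a.k_studies,
                "m": a.slope_m,
                "c": a.intercept_c,
                "var_m": a.cov_mc[0, 0] if a.cov_mc is not None else None,
                "var_c": a.cov_mc[1, 1] if a.cov_mc is not None else None,
                "cov_mc": a.cov_mc[0, 1] if a.cov_mc is not None else None,
                "tau2": a.tau2,
                "pooled_log_or": a.pooled_log_or,
                "pooled_se": a.pooled_se,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_association_csv(path: Path | str) -> list[PairAssociation]:
    df = _read_table(path)
    out = []
    for _, row in df.iterrows():
        mode = str(row["mode"])
        if mode == "metareg":
            cov = np.array(
                [
                    [float(row["var_m"]), float(row["cov_mc"])],
                    [float(row["cov_mc"]), float(row["var_c"])],
                ]
            )
            out.append(
                PairAssociation(
                    cond_a=str(row["cond_a"]),
                    cond_b=str(row["cond_b"]),
                    mode=mode,
                    k_studies=int(row["k_studies"]),
                    slope_m=float(row["m"]),
                    intercept_c=float(row["c"]),
                    cov_mc=cov,
                    tau2=float(row["tau2"]),
                )
            )
        else:
            out.append(
                PairAssociation(
                    cond_a=str(row["cond_a"]),
                    cond_b=str(row["cond_b"]),
                    mode=mode,
                    k_studies=int(row["k_studies"]),
                    pooled_log_or=float(row["pooled_log_or"]),
                    pooled_se=float(row["pooled_se"]),
                    tau2=float(row["tau2"]),
                )
            )
    return out


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    study_csv: Optional[Path] = None
    prevalence_csv: Optional[Path] = None
    fixed_or_csv: Optional[Path] = None
    out_dir: Path = Path("comorbid-out")
    units: str = "percent"
    seed: int = 0
    n_iter: int = 10_000
    ci_level: float = 0.95
    knapp_hartung: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("study_csv", "prevalence_csv", "fixed_or_csv", "out_dir"):
            val = getattr(cfg, name)
            if val is not None:
                setattr(cfg, name, Path(val))
        return cfg


@dataclass
class PipelineResult:
    """In-memory bundle of everything the pipeline computed."""

    associations: dict[tuple[str, str], PairAssociation]
    pair_prevalences: dict[tuple[str, str], PairPrevalence]
    pair_bootstraps: dict[tuple[str, str], PairBootstrap]
    profiles: dict[str, ComorbidityProfile]
    comorbidity_boots: dict[str, ComorbidityBootstrap]
    regression: Optional[tuple[float, float, float]]
    output_files: list[Path]


def _matrix(
    conditions: Sequence[str], values: dict[tuple[str, str], float], symmetric: bool
) -> pd.DataFrame:
    mat = pd.DataFrame(np.nan, index=list(conditions), columns=list(conditions))
    for (a, b), v in values.items():
        mat.loc[a, b] = v
        if symmetric:
            mat.loc[b, a] = v
    return mat


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Synthesis -> joint model -> bootstrap -> comorbidity summaries.

    Any stage failure aborts with a stage-tagged message and removes
    partially written outputs.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    written: list[Path] = []
    try:
        return _run_pipeline(cfg, written)
    except Exception:
        for f in written:
            try:
                f.unlink()
            except OSError:
                pass
        raise


def _run_pipeline(cfg: RunConfig, written: list[Path]) -> PipelineResult:
    stage = "read-inputs"
    try:
        if cfg.prevalence_csv is None:
            raise InputError("a prevalence table is required")
        prevalences = read_prevalence_csv(cfg.prevalence_csv, units=cfg.units)
        prev_by_cond = {p.condition: p for p in prevalences}
        records = read_study_csv(cfg.study_csv) if cfg.study_csv else []
        fixed = read_fixed_or_csv(cfg.fixed_or_csv) if cfg.fixed_or_csv else {}

        study_conds = {r.cond_a for r in records} | {r.cond_b for r in records}
        unknown = study_conds - set(prev_by_cond)
        if unknown:
            raise InputError(
                f"conditions in study table absent from prevalence table: {sorted(unknown)}"
            )

        stage = "synthesis"
        by_pair: dict[tuple[str, str], list[StudyRecord]] = {}
        for r in records:
            by_pair.setdefault(tuple(sorted((r.cond_a, r.cond_b))), []).append(r)
        pair_keys = sorted(set(by_pair) | set(fixed))
        if not pair_keys:
            raise InputError("no evidence: no study records and no fixed ORs supplied")
        associations: dict[tuple[str, str], PairAssociation] = {}
        for key in pair_keys:
            recs = by_pair.get(key, [])
            associations[key] = select_synthesis(
                recs,
                fixed_or=fixed.get(key) if not recs else None,
                cond_a=key[0],
                cond_b=key[1],
                knapp_hartung=cfg.knapp_hartung,
            )
            log.info("synthesised %s: mode=%s k=%d", key, associations[key].mode,
                     associations[key].k_studies)

        stage = "joint-model"
        pair_prev: dict[tuple[str, str], PairPrevalence] = {}
        for key, assoc in associations.items():
            a, b = assoc.cond_a, assoc.cond_b
            pair_prev[key] = pair_prevalence(prev_by_cond[a], prev_by_cond[b], assoc)

        stage = "bootstrap"
        boot_cfg = BootstrapConfig(n_iter=cfg.n_iter, ci_level=cfg.ci_level, seed=cfg.seed)
        ss = np.random.SeedSequence(cfg.seed)
        children = ss.spawn(len(pair_keys))
        pair_boots: dict[tuple[str, str], PairBootstrap] = {}
        for key, child in zip(pair_keys, children):
            assoc = associations[key]
            pb = bootstrap_pair(
                prev_by_cond[assoc.cond_a],
                prev_by_cond[assoc.cond_b],
                assoc,
                boot_cfg,
                rng=np.random.default_rng(child),
            )
            pair_boots[key] = pb
            pair_prev[key].ci_low = pb.ci_low
            pair_prev[key].ci_high = pb.ci_high

        stage = "comorbidity"
        conditions = sorted(prev_by_cond)
        profiles: dict[str, ComorbidityProfile] = {}
        como_boots: dict[str, ComorbidityBootstrap] = {}
        for cond in conditions:
            partner_pairs = [pp for k, pp in pair_prev.items() if cond in k]
            partners = {pp.partner_of(cond) for pp in partner_pairs}
            if partners != set(conditions) - {cond}:
                log.warning(
                    "skipping comorbidity profile for %s: incomplete pair coverage", cond
                )
                continue
            prof = comorbidity_profile(
                cond, partner_pairs, expected_partners=sorted(partners)
            )
            cb = bootstrap_comorbidity(
                cond,
                [pair_boots[k] for k in sorted(pair_boots) if cond in k],
                prof.m_expected,
                ci_level=cfg.ci_level,
            )
            prof.var_m, prof.ci_low, prof.ci_high = cb.var_m, cb.ci_low, cb.ci_high
            profiles[cond] = prof
            como_boots[cond] = cb

        regression = None
        if len(profiles) >= 3 and all(p.m_expected > 0 for p in profiles.values()):
            regression = fit_comorbidity_regression(
                list(profiles.values()), prevalences
            )

        stage = "write-reports"
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)

        def _write(df: pd.DataFrame, name: str, **kw) -> None:
            path = out / name
            df.to_csv(path, **kw)
            written.append(path)

        theta_mat = _matrix(
            conditions, {k: pp.theta_used for k, pp in pair_prev.items()}, symmetric=True
        )
        joint_mat = _matrix(
            conditions, {k: pp.p_joint for k, pp in pair_prev.items()}, symmetric=True
        )
        cond_vals: dict[tuple[str, str], float] = {}
        for k, pp in pair_prev.items():
            cond_vals[(pp.cond_a, pp.cond_b)] = pp.p_b_given_a
            cond_vals[(pp.cond_b, pp.cond_a)] = pp.p_a_given_b
        cond_mat = _matrix(conditions, cond_vals, symmetric=False)
        _write(theta_mat, "odds_ratio_matrix.csv")
        _write(joint_mat, "joint_prevalence_matrix.csv")
        _write(cond_mat, "conditional_matrix.csv")

        pair_rows = []
        for key in pair_keys:
            pp, pb, assoc = pair_prev[key], pair_boots[key], associations[key]
            pair_rows.append(
                {
                    "cond_a": pp.cond_a,
                    "cond_b": pp.cond_b,
                    "mode": assoc.mode,
                    "k_studies": assoc.k_studies,
                    "theta_point": pp.theta_used,
                    "theta_boot_mean": float(np.mean(pb.theta)),
                    "theta_ci_low": pb.theta_ci_low,
                    "theta_ci_high": pb.theta_ci_high,
                    "p_joint": pp.p_joint,
                    "p_joint_pct": 100.0 * pp.p_joint,
                    "ci_low": pp.ci_low,
                    "ci_high": pp.ci_high,
                    "p_b_given_a": pp.p_b_given_a,
                    "p_a_given_b": pp.p_a_given_b,
                }
            )
        _write(pd.DataFrame(pair_rows), "pairs.csv", index=False)

        como_rows = [
            {
                "condition": cond,
                "m_expected": prof.m_expected,
                "ci_low": prof.ci_low,
                "ci_high": prof.ci_high,
                "percentile_ci_low": como_boots[cond].percentile_ci_low,
                "percentile_ci_high": como_boots[cond].percentile_ci_high,
                "var_m": prof.var_m,
            }
            for cond, prof in profiles.items()
        ]
        _write(pd.DataFrame(como_rows), "comorbidity.csv", index=False)

        write_association_csv(list(associations.values()), out / "associations.csv")
        written.append(out / "associations.csv")

        manifest = {
            "package": "comorbid",
            "version": __version__,
            "seed": cfg.seed,
            "n_iter": cfg.n_iter,
            "ci_level": cfg.ci_level,
            "units": cfg.units,
            "inputs": {
                "study_csv": str(cfg.study_csv) if cfg.study_csv else None,
                "prevalence_csv": str(cfg.prevalence_csv),
                "fixed_or_csv": str(cfg.fixed_or_csv) if cfg.fixed_or_csv else None,
            },
            "n_pairs": len(pair_keys),
            "n_profiles": len(profiles),
            "regression": None
            if regression is None
            else dict(zip(("slope", "factor_per_10pct", "pearson_r"), regression)),
        }
        manifest_path = out / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(manifest_path)

        return PipelineResult(
            associations=associations,
            pair_prevalences=pair_prev,
            pair_bootstraps=pair_boots,
            profiles=profiles,
            comorbidity_boots=como_boots,
            regression=regression,
            output_files=list(written),
        )
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
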