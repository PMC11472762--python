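"""Orchestration: merge/clean bird records and run the full analysis.

The analysis consumes one combined sheet per flock (bird ID keyed):
longitudinal radiographic measurements at the five live ages plus the
two post-mortem points, body weight, pelvic dimensions, and the
dissected keel scores.  :func:`run_all` reproduces the study's result
surfaces from such a sheet (real or simulated):

* score-variable frequency tables and damage co-frequencies,
* the polychoric/polyserial correlation matrix among dissected keel
  variables,
* longitudinal Pearson matrices for the three radiographic variables,
* Tukey-letter comparisons of the dissected length:mid-depth ratio
  across damage score groups,
* per-age damage-model coefficient tables (linear / logistic /
  censored Poisson) and pelvic-dimension interaction models,

writing each as CSV plus a JSON run manifest.  The pipeline is a pure
function of (input sheet, config, seed).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_stats as astats
from . import keel_scoring as scoring
from . import regression_models as regmod
from .radiograph_io import TIMEPOINTS
from .synthetic_data import (FlockSimParams, flock_to_scores, read_sm1_like,
                             simulate_flock)

log = logging.getLogger("keelmorph")

SCORE_COLUMNS = [
    "deviation_size", "deviation_loc", "deviation_extent",
    "fracture_count", "fracture_censored", "fracture_loc", "fracture_extent",
    "callus_size", "callus_loc", "callus_extent",
    "keel_length_cm", "keel_mid_depth_cm",
]

#: dissected variables entering the correlation matrix, marked by type
DISSECT_ORDINAL = ("deviation_size", "deviation_extent", "fracture_count",
                   "fracture_extent", "callus_size", "callus_extent")
DISSECT_CONTINUOUS = ("keel_length_cm", "keel_mid_depth_cm", "length_mid_depth")

LONGITUDINAL_VARS = ("tibio_density", "keel_density", "xlm")


# ---------------------------------------------------------------------------
# Merge and clean

def merge_clean(
    measurements: pd.DataFrame,
    scores: pd.DataFrame,
    pelvic: pd.DataFrame,
    required: list[str] | None = None,
    strict: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inner-join the three sources on bird ID and drop incomplete birds.

    ``strict`` reproduces a single globally cleaned set: a bird missing
    any required value anywhere is excluded; with ``strict=False`` only
    the ID requirement applies and per-analysis dropna handles the rest.
    Returns ``(records, exclusion_log)`` where the log has one row per
    excluded bird with the reason.
    """
    exclusions = []
    frames = {"measurements": measurements, "scores": scores, "pelvic": pelvic}
    cleaned = {}
    for name, df in frames.items():
        df = df.copy()
        if "bird_id" not in df.columns:
            raise ValueError(f"{name}: missing bird_id column")
        bad_id = df["bird_id"].isna() | (df["bird_id"].astype(str).str.strip() == "")
        for _ in range(int(bad_id.sum())):
            exclusions.append({"bird_id": "<missing>", "source": name,
                               "reason": "missing or unclear bird ID"})
        df = df[~bad_id]
        dup = df["bird_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"{name}: duplicate bird_id values: "
                f"{sorted(df.loc[dup, 'bird_id'].unique())[:5]}")
        cleaned[name] = df

    merged = cleaned["measurements"].merge(
        cleaned["scores"], on="bird_id", how="inner",
        suffixes=("", "_score"))
    merged = merged.merge(cleaned["pelvic"], on="bird_id", how="inner",
                          suffixes=("", "_pelvic"))
    all_ids = set().union(*(set(df["bird_id"]) for df in cleaned.values()))
    for bid in sorted(all_ids - set(merged["bird_id"])):
        missing_from = [n for n, df in cleaned.items()
                        if bid not in set(df["bird_id"])]
        exclusions.append({"bird_id": bid, "source": ",".join(missing_from),
                           "reason": "absent from source(s)"})

    if strict:
        req = required if required is not None else [
            c for c in merged.columns
            if pd.api.types.is_numeric_dtype(merged[c]) or
            pd.api.types.is_bool_dtype(merged[c])]
        incomplete = merged[req].isna().any(axis=1)
        for bid in merged.loc[incomplete, "bird_id"]:
            cols = merged.columns[merged.loc[
                merged["bird_id"] == bid, :].isna().any()].tolist()
            exclusions.append({"bird_id": bid, "source": "merged",
                               "reason": f"missing values: {cols[:4]}"})
        merged = merged[~incomplete]

    log.info("merge_clean: %d birds retained, %d exclusions",
             len(merged), len(exclusions))
    return merged.reset_index(drop=True), pd.DataFrame(
        exclusions, columns=["bird_id", "source", "reason"])


def split_flock(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a combined (SM1-like) frame into the three merge sources."""
    meas_cols = ["bird_id"] + [
        c for c in df.columns
        if any(c.startswith(f"{v}_") for v in LONGITUDINAL_VARS)
        or c.startswith("bodyweight_")]
    score_cols = ["bird_id", "operator", "laying_status"] + [
        c for c in SCORE_COLUMNS if c in df.columns]
    pelvic_cols = ["bird_id", "pelvic_width", "pelvic_depth", "pelvic_capacity"]
    return df[meas_cols].copy(), df[score_cols].copy(), df[pelvic_cols].copy()


# ---------------------------------------------------------------------------
# Analysis stages

def _dissect_frame(records: pd.DataFrame) -> pd.DataFrame:
    d = records.copy()
    d["length_mid_depth"] = d["keel_length_cm"] / d["keel_mid_depth_cm"]
    return d


def score_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Table-2-style per-category frequencies of every score variable."""
    sc = flock_to_scores(records)
    rows = []
    for var in scoring.ORDINAL_VARIABLES:
        for cat, prop in scoring.frequency_table(sc, var).items():
            rows.append({"variable": var, "category": cat,
                         "proportion": prop})
    return pd.DataFrame(rows)


def damage_summary(records: pd.DataFrame) -> dict:
    """Headline prevalence and damage co-frequencies."""
    sc = flock_to_scores(records)
    return {
        "n": len(sc),
        "damage_prevalence": scoring.damage_prevalence(sc),
        "deviation_prevalence": scoring.co_frequency(
            sc, "deviation_size", "deviation_size"),
        "fracture_prevalence": scoring.co_frequency(
            sc, "fracture_count", "fracture_count"),
        "callus_prevalence": scoring.co_frequency(
            sc, "callus_size", "callus_size"),
        "cofreq_fracture_callus": scoring.co_frequency(
            sc, "fracture_count", "callus_size"),
        "cofreq_deviation_fracture": scoring.co_frequency(
            sc, "deviation_size", "fracture_count"),
    }


def dissect_correlation_matrix(records: pd.DataFrame) -> pd.DataFrame:
    """Table-3-style matrix: polychoric among ordinal score variables,
    polyserial between ordinal and continuous, Pearson among continuous."""
    d = _dissect_frame(records)
    variables = list(DISSECT_ORDINAL) + list(DISSECT_CONTINUOUS)
    rows = []
    for i, a in enumerate(variables):
        for b in variables[:i]:
            xa, xb = d[a].to_numpy(float), d[b].to_numpy(float)
            mask = np.isfinite(xa) & np.isfinite(xb)
            xa, xb = xa[mask], xb[mask]
            a_ord = a in DISSECT_ORDINAL
            b_ord = b in DISSECT_ORDINAL
            try:
                if a_ord and b_ord:
                    est = astats.polychoric(xa, xb)
                elif a_ord != b_ord:
                    cont, ordi = (xb, xa) if a_ord else (xa, xb)
                    est = astats.polyserial(cont, ordi)
                else:
                    est = astats.pearson_with_se(xa, xb)
            except ValueError as exc:
                log.warning("correlation %s vs %s skipped: %s", a, b, exc)
                continue
            rows.append({"var_a": a, "var_b": b, "rho": est.rho,
                         "se": est.se, "method": est.method, "n": est.n,
                         "at_boundary": est.at_boundary})
    return pd.DataFrame(rows)


def longitudinal_matrices(
    records: pd.DataFrame,
    variables=LONGITUDINAL_VARS,
    pool_live_postmortem: bool = True,
) -> dict[str, dict[str, pd.DataFrame]]:
    """Table-4-style cross-age Pearson matrices per radiographic variable.

    Live and post-mortem cells are kept in one matrix by default (the
    correlations are scale-free even though the machine was
    re-calibrated between them); ``pool_live_postmortem=False``
    restricts to the live ages.
    """
    tps = list(TIMEPOINTS) if pool_live_postmortem else list(TIMEPOINTS[:5])
    out = {}
    for var in variables:
        cols = {tp: f"{var}_{tp}" for tp in tps if f"{var}_{tp}" in records}
        wide = records[list(cols.values())].rename(
            columns={v: k for k, v in cols.items()})
        out[var] = astats.longitudinal_matrix(wide, list(cols))
    return out


def ratio_group_comparisons(records: pd.DataFrame) -> dict[str, astats.TukeyGroups]:
    """Dissected length:mid-depth ratio across damage score groups."""
    d = _dissect_frame(records)
    out = {}
    for var in ("deviation_size", "fracture_count", "callus_size"):
        out[var] = astats.group_means_tukey(
            d["length_mid_depth"].to_numpy(float), d[var].to_numpy())
    return out


def _long_records(records: pd.DataFrame, timepoint: str) -> pd.DataFrame:
    """Per-age modelling frame with the four radiographic predictors."""
    cols = {
        "tibiotarsal": f"tibio_density_{timepoint}",
        "keel": f"keel_density_{timepoint}",
        "xlm": f"xlm_{timepoint}",
        "bodyweight": f"bodyweight_{timepoint}",
    }
    missing = [c for c in cols.values() if c not in records.columns]
    if missing:
        raise ValueError(f"missing predictor columns {missing}")
    out = records[["bird_id", "operator"]].copy()
    for new, old in cols.items():
        out[new] = records[old].to_numpy(float)
    for c in SCORE_COLUMNS:
        if c in records.columns:
            out[c] = records[c].to_numpy()
    out["deviation_present"] = (records["deviation_size"] > 0).astype(int)
    return out


def damage_models_by_age(
    records: pd.DataFrame,
    responses: dict[str, str] | None = None,
    timepoints=TIMEPOINTS,
) -> pd.DataFrame:
    """Figs-6/7-style tables: damage regressions per age and response.

    ``responses`` maps response column to family; the default covers
    deviation size and extents (linear), fracture count (censored
    Poisson), and presence of deviation (logistic).
    """
    if responses is None:
        responses = {
            "deviation_size": "linear",
            "deviation_extent": "linear",
            "fracture_extent": "linear",
            "fracture_count": "censored_poisson",
            "deviation_present": "logistic",
        }
    rows = []
    for tp in timepoints:
        base = _long_records(records, tp)
        for resp, family in responses.items():
            try:
                res = regmod.damage_model(base, resp, family=family)
            except ValueError as exc:
                log.warning("damage model %s @ %s failed: %s", resp, tp, exc)
                continue
            t = res.tidy()
            t.insert(0, "timepoint", tp)
            t.insert(1, "response", resp)
            rows.append(t)
    return pd.concat(rows, ignore_index=True)


def pelvic_models(
    records: pd.DataFrame,
    response_timepoint: str = "PM",
    responses=("keel_density", "keel_mid_depth", "deviation_size",
               "fracture_count"),
) -> pd.DataFrame:
    """Fig-8-style table: keel condition on pelvic dims x tibiotarsal."""
    base = records[["bird_id", "operator", "pelvic_width", "pelvic_depth",
                    "pelvic_capacity"]].copy()
    base["tibiotarsal"] = records[f"tibio_density_{response_timepoint}"]
    base["bodyweight"] = records[f"bodyweight_{response_timepoint}"]
    base["keel_density"] = records[f"keel_density_{response_timepoint}"]
    if "keel_mid_depth_cm" in records:
        base["keel_mid_depth"] = records["keel_mid_depth_cm"]
    for c in ("deviation_size", "fracture_count"):
        if c in records:
            base[c] = records[c]
    rows = []
    for resp in responses:
        if resp not in base.columns:
            continue
        fits = regmod.pelvic_model(base, resp, "all")
        for pv, res in fits.items():
            t = res.tidy()
            t.insert(0, "response", resp)
            t.insert(1, "pelvic_variable", pv)
            rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# run_all

DEFAULT_CONFIG = {
    "seed": 0,
    "n_birds": 155,
    "input": None,          # path to an SM1-like sheet, or None to simulate
    "outdir": "results",
    "pool_live_postmortem": True,
    "analyses": ["frequencies", "correlations", "longitudinal",
                 "tukey", "damage_models", "pelvic_models"],
}


def run_all(config: dict | str | Path) -> dict:
    """Run the complete analysis and write the results bundle.

    ``config`` is a dict (or path to a YAML file) with the
    :data:`DEFAULT_CONFIG` keys.  Outputs are deterministic for a given
    (input, config, seed).  Returns the manifest.
    """
    if not isinstance(config, dict):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bad = set(cfg["analyses"]) - set(DEFAULT_CONFIG["analyses"])
    if bad:
        raise ValueError(f"unknown analyses requested: {sorted(bad)}")

    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg["input"] is None:
        combined = simulate_flock(FlockSimParams(
            n_birds=int(cfg["n_birds"]), seed=int(cfg["seed"])))
    else:
        combined = read_sm1_like(cfg["input"])
    meas, sc, pel = split_flock(combined)
    records, excl = merge_clean(meas, sc, pel)

    written: list[str] = []

    def _write(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(name)

    _write(excl, "exclusions.csv")
    try:
        if "frequencies" in cfg["analyses"]:
            _write(score_frequencies(records), "frequencies.csv")
            summary = damage_summary(records)
            with open(outdir / "damage_summary.json", "w") as fh:
                json.dump(summary, fh, indent=1)
            written.append("damage_summary.json")
        if "correlations" in cfg["analyses"]:
            _write(dissect_correlation_matrix(records), "dissect_correlations.csv")
        if "longitudinal" in cfg["analyses"]:
            mats = longitudinal_matrices(
                records, pool_live_postmortem=cfg["pool_live_postmortem"])
            rows = []
            for var, m in mats.items():
                for a in m["rho"].index:
                    for b in m["rho"].columns:
                        if np.isfinite(m["rho"].loc[a, b]):
                            rows.append({
                                "variable": var, "row": a, "col": b,
                                "rho": m["rho"].loc[a, b],
                                "se": m["se"].loc[a, b],
                                "n": int(m["n"].loc[a, b])})
            _write(pd.DataFrame(rows), "longitudinal_correlations.csv")
        if "tukey" in cfg["analyses"]:
            rows = []
            for var, tg in ratio_group_comparisons(records).items():
                for g in tg.groups:
                    rows.append({"group_variable": var, "group": g,
                                 "mean_ratio": tg.means[g], "n": tg.n[g],
                                 "letters": tg.letters[g],
                                 "anova_p": tg.anova_p})
            _write(pd.DataFrame(rows), "ratio_tukey.csv")
        if "damage_models" in cfg["analyses"]:
            _write(damage_models_by_age(records), "damage_models.csv")
        if "pelvic_models" in cfg["analyses"]:
            _write(pelvic_models(records), "pelvic_models.csv")
    except Exception as exc:
        for p in outdir.glob("*.csv"):
            p.unlink()
        for p in outdir.glob("*.json"):
            p.unlink()
        raise RuntimeError(f"analysis stage failed; partial outputs removed: "
                           f"{exc}") from exc

    import keelmorph

    manifest = {
        "seed": int(cfg["seed"]),
        "n_birds_input": int(len(combined)),
        "n_birds_retained": int(len(records)),
        "n_exclusions": int(len(excl)),
        "input": cfg["input"] or "simulated",
        "analyses": cfg["analyses"],
        "outputs": written,
        "version": keelmorph.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
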