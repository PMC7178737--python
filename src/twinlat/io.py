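"""Study file I/O, validation and the end-to-end analysis pipeline.

CSV dialect: UTF-8, comma-separated, header row required, empty string =
missing.  Report tables are written as TSV with fixed display precision
(3 dp for proportions/components, 2 dp for chi-square and delta -2LL);
JSON summaries carry full precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from . import prevalence as prev
from . import scoring
from . import twin

__all__ = ["StudyData", "ValidationError", "RunConfig", "read_study", "make_twin_wide", "run_pipeline"]

logger = logging.getLogger("twinlat")

_HAND_VOCAB = {"left", "right", "either"}
_DEGREE_VOCAB = {"always", "usually", ""}
_SEX_VOCAB = {"male", "female"}
_COHORT_VOCAB = {"twin", "singleton"}


class ValidationError(ValueError):
    """Raised when input files fail schema or invariant checks."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__(
            "study validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems)
        )


@dataclass
class StudyData:
    items: pd.DataFrame
    pegs: pd.DataFrame
    roster: pd.DataFrame
    warnings: list = field(default_factory=list)


@dataclass
class RunConfig:
    """Pipeline configuration.

    ``models`` toggles the univariate fits; ``bivariate`` the Cholesky
    ladder; ``prevalence`` the contingency/ANOVA/correlation reports.
    """

    items_path: str = "items.csv"
    pegs_path: str = "pegs.csv"
    roster_path: str = "roster.csv"
    out_dir: str = "reports"
    run_prevalence: bool = True
    run_univariate: bool = True
    run_bivariate: bool = True
    ss_type: int = 3
    corrected_item_total: bool = False
    n_restarts: int = 5
    seed: int = 0
    measures: tuple = ("writing_bin", "drawing_bin", "EHI", "EHI2", "PegQ", "PegQ2")


def _require_columns(df, cols, name, problems):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        problems.append(f"{name}: missing columns {missing}")
    return not missing


def read_study(items_path, pegs_path, roster_path) -> StudyData:
    """Load and validate the three study CSVs.

    Row-level problems (unknown vocabulary, duplicate responses, MZ pairs
    with discordant sexes) are collected and reported together; loading
    fails only when any problem is found or a file is unusable.
    """
    problems: list[str] = []
    items = pd.read_csv(items_path, dtype=str, keep_default_na=False)
    pegs = pd.read_csv(pegs_path)
    roster = pd.read_csv(roster_path, dtype=str, keep_default_na=False)

    if _require_columns(items, ["subject_id", "item_id", "hand", "degree"], "items", problems):
        for i, row in enumerate(items.itertuples(index=False), start=2):
            if row.item_id not in scoring.ITEMS:
                problems.append(f"items line {i}: unknown item_id {row.item_id!r}")
            if row.hand not in _HAND_VOCAB:
                problems.append(f"items line {i}: unknown hand {row.hand!r}")
            elif row.hand != "either" and row.degree not in ("always", "usually"):
                problems.append(f"items line {i}: unknown degree {row.degree!r}")
        dup = items.duplicated(subset=["subject_id", "item_id"])
        for i in np.flatnonzero(dup.to_numpy()):
            problems.append(f"items line {i + 2}: duplicate response for item")

    if _require_columns(
        pegs, ["subject_id", "hand", "trial_index", "time_seconds"], "pegs", problems
    ):
        bad_hand = ~pegs["hand"].isin(["left", "right"])
        for i in np.flatnonzero(bad_hand.to_numpy()):
            problems.append(f"pegs line {i + 2}: hand must be left/right")
        bad_time = ~(pd.to_numeric(pegs["time_seconds"], errors="coerce") > 0)
        for i in np.flatnonzero(bad_time.to_numpy()):
            problems.append(f"pegs line {i + 2}: non-positive or non-numeric time")

    if _require_columns(
        roster, ["subject_id", "cohort", "sex", "age", "pair_id", "zygosity"], "roster", problems
    ):
        for i, row in enumerate(roster.itertuples(index=False), start=2):
            if row.cohort not in _COHORT_VOCAB:
                problems.append(f"roster line {i}: unknown cohort {row.cohort!r}")
            if row.sex not in _SEX_VOCAB:
                problems.append(f"roster line {i}: unknown sex {row.sex!r}")
            if row.cohort == "twin" and row.zygosity not in ("MZ", "DZ"):
                problems.append(f"roster line {i}: twin without MZ/DZ zygosity")
        twins = roster[roster["cohort"] == "twin"]
        for pair_id, grp in twins.groupby("pair_id"):
            if len(grp) == 2:
                z = grp["zygosity"].iloc[0]
                if z == "MZ" and grp["sex"].nunique() != 1:
                    problems.append(f"roster pair {pair_id}: MZ pair with discordant sexes")

    if problems:
        raise ValidationError(problems)
    roster = roster.assign(age=pd.to_numeric(roster["age"], errors="coerce"))
    items = items.assign(degree=items["degree"].replace("", np.nan))
    return StudyData(items=items, pegs=pegs, roster=roster)


def make_twin_wide(scored: pd.DataFrame, roster: pd.DataFrame, measures) -> pd.DataFrame:
    """Pivot per-subject scores into one row per twin pair.

    Columns: pair_id, zygosity, sex1, sex2, age, then ``<measure>_t1`` /
    ``<measure>_t2`` for each requested measure.  Twin order follows the
    subject_id sort within a pair.  Pairs where one twin lacks all
    measures keep that twin's entries as NaN.
    """
    twins = roster[roster["cohort"] == "twin"].merge(scored, on="subject_id", how="left")
    twins = twins.sort_values(["pair_id", "subject_id"])
    rows = []
    for pair_id, grp in twins.groupby("pair_id"):
        rec = {
            "pair_id": pair_id,
            "zygosity": grp["zygosity"].iloc[0],
            "age": grp["age"].iloc[0],
        }
        for j in range(2):
            rec[f"sex{j + 1}"] = grp["sex"].iloc[j] if len(grp) > j else np.nan
            for m in measures:
                rec[f"{m}_t{j + 1}"] = grp[m].iloc[j] if len(grp) > j else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


_BINARY_MEASURES = {"writing_bin", "drawing_bin", "EHI2", "PegQ2"}


def _fmt(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            if col in ("chi2", "delta_ll", "minus2ll", "aic", "F"):
                out[col] = out[col].round(2)
            else:
                out[col] = out[col].round(3)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Score the study and run the requested analyses; write report files.

    Returns a dict of output paths.  Raises on validation failure; any
    stage error propagates with the stage named in the log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    from . import __version__

    summary: dict = {
        "config": {k: str(v) for k, v in vars(config).items()},
        "seed": config.seed,
        "versions": {
            "twinlat": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }

    logger.info("stage=read")
    study = read_study(config.items_path, config.pegs_path, config.roster_path)

    logger.info("stage=score")
    scored = scoring.score_study(study.items, study.pegs)
    paths["scored"] = str(out / "scored.csv")
    scored.to_csv(paths["scored"], index=False)

    if config.run_prevalence:
        logger.info("stage=prevalence")
        classes = study.items.copy()
        classes["pref_class"] = [
            scoring.recode_item_three_class(
                scoring.ItemResponse(r.item_id, r.hand, None if pd.isna(r.degree) else r.degree)
            )
            for r in classes.itertuples(index=False)
        ]
        pref = prev.preference_tables(
            classes[["subject_id", "item_id", "pref_class"]], study.roster
        )
        paths["preference_tests"] = str(out / "preference_tests.tsv")
        _fmt(pref).to_csv(paths["preference_tests"], sep="\t", index=False)

        direction = prev.direction_tables(scored, study.roster)
        paths["direction_tests"] = str(out / "direction_tests.tsv")
        _fmt(direction).to_csv(paths["direction_tests"], sep="\t", index=False)

        merged = scored.merge(study.roster, on="subject_id")
        anova_rows = []
        for measure in ("EHI", "PegQ"):
            sub = merged.dropna(subset=[measure])
            res = prev.anova_two_way(
                sub[measure], sub["cohort"], sub["sex"], ss_type=config.ss_type
            )
            tab = res.table.reset_index(names="effect")
            tab.insert(0, "measure", measure)
            anova_rows.append(tab)
        anova = pd.concat(anova_rows, ignore_index=True)
        paths["anova"] = str(out / "anova.tsv")
        _fmt(anova).to_csv(paths["anova"], sep="\t", index=False)

        corr_cols = ["age"] + [m for m in config.measures if m in merged.columns]
        corr_in = merged[corr_cols].copy()
        corr_in.insert(1, "sex", (merged["sex"] == "female").astype(int))
        r, p = prev.correlation_matrix(corr_in)
        paths["correlations"] = str(out / "correlations.tsv")
        _fmt(r.reset_index(names="measure")).to_csv(paths["correlations"], sep="\t", index=False)

        # reliability of the inventory on signed item scores
        item_scores = _item_score_frame(study.items)
        summary["cronbach_alpha"] = prev.cronbach_alpha(item_scores)
        summary["item_total_r"] = prev.item_total_correlations(
            item_scores, corrected=config.corrected_item_total
        ).to_dict()

    wide = make_twin_wide(scored, study.roster, config.measures)

    if config.run_univariate:
        logger.info("stage=univariate")
        rows = []
        for measure in config.measures:
            kind = "binary_liability" if measure in _BINARY_MEASURES else "continuous"
            fits = {}
            for comps in ("ACE", "AE", "CE", "E"):
                model = twin.UnivariateTwinModel(
                    components=comps,
                    trait_kind=kind,
                    n_restarts=config.n_restarts,
                    random_state=config.seed,
                ).fit(wide, cols=(f"{measure}_t1", f"{measure}_t2"))
                fits[comps] = model
            ace = fits["ACE"]
            row = {
                "measure": measure,
                "a2": ace.a2_,
                "c2": ace.c2_,
                "e2": ace.e2_,
                "minus2ll": ace.minus2ll_,
                "df": ace.df_,
            }
            for comps in ("AE", "CE", "E"):
                delta, ddf, p = twin.lrt(ace, fits[comps])
                row[f"minus2ll_{comps}"] = fits[comps].minus2ll_
                row[f"delta_ll_{comps}"] = delta
                row[f"p_{comps}"] = p
            rows.append(row)
        uni = pd.DataFrame(rows)
        paths["univariate"] = str(out / "univariate_fits.tsv")
        _fmt(uni).to_csv(paths["univariate"], sep="\t", index=False)
        summary["univariate"] = uni.to_dict(orient="records")

    if config.run_bivariate:
        logger.info("stage=bivariate")
        ladder = twin.fit_bivariate_ladder(
            wide,
            cols=(("EHI_t1", "EHI_t2"), ("PegQ_t1", "PegQ_t2")),
            n_restarts=config.n_restarts,
            random_state=config.seed,
        )
        paths["bivariate"] = str(out / "bivariate_ladder.tsv")
        _fmt(ladder.comparison).to_csv(paths["bivariate"], sep="\t", index=False)
        best = ladder.fits[ladder.best]
        cf = best.to_correlated_factors()
        summary["bivariate"] = {
            "best_model": ladder.best,
            "a2": list(best.a2_),
            "c2": list(best.c2_),
            "e2": list(best.e2_),
            "r_a": cf.r_a,
            "r_c": cf.r_c,
            "r_e": cf.r_e,
        }

    paths["summary"] = str(out / "summary.json")
    Path(paths["summary"]).write_text(json.dumps(_jsonify(summary), indent=2))
    logger.info("stage=done")
    return paths


def _jsonify(obj):
    """Plain-JSON view: numpy scalars to Python, NaN to null."""
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, np.integer):
        return int(obj)
    return obj


def _item_score_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Subjects x items matrix of signed point scores (right - left points)."""

    def signed(row):
        resp = scoring.ItemResponse(
            row.item_id, row.hand, None if pd.isna(row.degree) else row.degree
        )
        pts = scoring.score_item(resp)
        return pts.right - pts.left

    df = items.copy()
    df["score"] = [signed(r) for r in df.itertuples(index=False)]
    return df.pivot(index="subject_id", columns="item_id", values="score")
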