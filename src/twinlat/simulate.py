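"""Synthetic twin/singleton handedness cohorts.

The generator inverts the models the analysis stages assume, so the whole
pipeline is testable end-to-end without participant data:

* latent trait liabilities follow the bivariate ACE structure (additive-
  genetic factors correlated 1 in MZ and 0.5 in DZ pairs, shared
  environment common to co-twins, non-shared environment independent),
  with configurable cross-trait factor correlations rA, rC, rE;
* binary handedness arises by thresholding the liability at
  tau = Phi^-1(prevalence of the non-right class), with an optional male
  excess entering as a liability mean shift calibrated from an odds ratio;
* questionnaire items follow a graded-response structure: each item reads
  the preference liability through its own loading and cuts a unit-variance
  item liability at symmetric thresholds into the five ordered answers
  (always/usually left, either, usually/always right).  High-loading pen
  items and low-loading broom/box-lid items reproduce the J-shaped
  composite with roughly 8% non-right-handers;
* pegboard trials are per-hand true movement times with a laterality-
  linked asymmetry plus i.i.d. trial noise, tuned so the population PegQ
  index is centred near 0.095 with spread near 0.10.

Everything is deterministic given the seed: one root ``SeedSequence`` is
split per sub-generator, and within each stream draws are vectorized in
subject order, so enlarging a cohort never perturbs earlier subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import ITEMS

__all__ = [
    "SimulationConfig",
    "simulate_pairs",
    "simulate_binary",
    "simulate_ehi_items",
    "simulate_peg_trials",
    "simulate_cohort",
    "write_cohort",
]


def _default_item_params() -> dict:
    # (loading, either half-width t1, always threshold t2); loadings ordered
    # so pen tasks read the liability most faithfully and the ambiguous
    # broom/box-lid items least
    return {
        "writing": (0.95, 0.05, 0.55),
        "drawing": (0.93, 0.15, 0.65),
        "throwing": (0.60, 0.70, 1.60),
        "scissors": (0.75, 0.28, 1.10),
        "toothbrush": (0.65, 0.50, 1.40),
        "chopsticks": (0.85, 0.08, 0.70),
        "spoon": (0.68, 0.52, 1.40),
        "knife": (0.62, 0.27, 1.30),
        "broom": (0.50, 0.45, 1.50),
        "box_lid": (0.50, 0.80, 1.80),
    }


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic cohort.

    Sample sizes and composition mirror the study being emulated: 91 MZ and
    114 DZ twin pairs plus 426 age/sex-matched singletons.  Trait 1 is the
    hand-preference liability behind the questionnaire (standardized
    a2 = .205), trait 2 the pegboard-skill liability (a2 = .217); shared
    environment is absent and the phenotypic cross-trait correlation of
    about .42 is carried entirely by the non-shared environmental factors
    (r_e = .53 = .42 / sqrt(e1^2 e2^2)), the best-supported structure for
    these measures.
    """

    n_mz: int = 91
    n_dz: int = 114
    n_singletons: int = 426
    a2: tuple = (0.205, 0.217)
    c2: tuple = (0.0, 0.0)
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.53
    nrh_prevalence: float = 0.08
    male_nrh_odds_ratio: float = 1.27
    # pair-type mix (study proportions): MZ male fraction; DZ mm/ff/os
    p_mz_male: float = 41 / 91
    p_dz_mix: tuple = (25 / 114, 21 / 114, 68 / 114)
    p_singleton_male: float = 221 / 426
    twin_age: tuple = (8.7, 1.2, 6.7, 12.2)  # mean, sd, min, max
    singleton_age: tuple = (8.3, 1.2, 6.3, 12.0)
    item_params: dict = field(default_factory=_default_item_params)
    peg_mean_time: float = 13.0
    peg_between_sd: float = 2.0
    peg_trial_sd: float = 0.5
    pegq_mean: float = 0.095
    pegq_sd: float = 0.097
    n_trials: int = 5
    seed: Optional[int] = None

    def validate(self) -> None:
        for t, (a2, c2) in enumerate(zip(self.a2, self.c2), start=1):
            if not (0 <= a2 and 0 <= c2 and a2 + c2 <= 1):
                raise ValueError(f"trait {t}: need a2, c2 >= 0 and a2 + c2 <= 1")
        for r in (self.r_a, self.r_c, self.r_e):
            if not -1 <= r <= 1:
                raise ValueError("factor correlations must be in [-1, 1]")
        if not 0 < self.nrh_prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if min(self.n_mz, self.n_dz, self.n_singletons) < 0:
            raise ValueError("sample sizes must be non-negative")
        for item, (lam, t1, t2) in self.item_params.items():
            if not (0 < lam <= 1 and 0 <= t1 < t2):
                raise ValueError(f"item {item}: need 0 < loading <= 1 and 0 <= t1 < t2")


def _streams(seed, names):
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _factor_chol(r: float) -> np.ndarray:
    return np.linalg.cholesky(np.array([[1.0, r], [r, 1.0]]))


def _draw_factor(rng, n, chol) -> np.ndarray:
    return rng.standard_normal((n, 2)) @ chol.T


def implied_twin_correlations(a2, c2) -> tuple[float, float]:
    """Phenotypic MZ and DZ twin correlations implied by the components."""
    return a2 + c2, 0.5 * a2 + c2


def simulate_pairs(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    n_mz: Optional[int] = None,
    n_dz: Optional[int] = None,
) -> pd.DataFrame:
    """Standardized bivariate trait liabilities for MZ and DZ twin pairs.

    Returns one row per pair: pair_id, zygosity, and liab{1,2}_t{1,2}
    columns with zero mean and unit variance, whose covariance structure is
    the configured bivariate ACE model.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    n_mz = config.n_mz if n_mz is None else n_mz
    n_dz = config.n_dz if n_dz is None else n_dz
    a = np.sqrt(np.asarray(config.a2))
    c = np.sqrt(np.asarray(config.c2))
    e = np.sqrt(1.0 - np.asarray(config.a2) - np.asarray(config.c2))
    La, Lc, Le = _factor_chol(config.r_a), _factor_chol(config.r_c), _factor_chol(config.r_e)

    def compose(A1, A2, C, E1, E2):
        y1 = a * A1 + c * C + e * E1
        y2 = a * A2 + c * C + e * E2
        return y1, y2

    # MZ: one genetic draw per pair
    A = _draw_factor(rng, n_mz, La)
    C = _draw_factor(rng, n_mz, Lc)
    E1, E2 = _draw_factor(rng, n_mz, Le), _draw_factor(rng, n_mz, Le)
    mz1, mz2 = compose(A, A, C, E1, E2)

    # DZ: additive-genetic correlation 0.5 via a common and a unique part
    Ac = _draw_factor(rng, n_dz, La)
    Au1, Au2 = _draw_factor(rng, n_dz, La), _draw_factor(rng, n_dz, La)
    s = np.sqrt(0.5)
    A1, A2 = s * Ac + s * Au1, s * Ac + s * Au2
    C = _draw_factor(rng, n_dz, Lc)
    E1, E2 = _draw_factor(rng, n_dz, Le), _draw_factor(rng, n_dz, Le)
    dz1, dz2 = compose(A1, A2, C, E1, E2)

    frames = []
    for z, (y1, y2), offset in (("MZ", (mz1, mz2), 0), ("DZ", (dz1, dz2), n_mz)):
        n = len(y1)
        frames.append(
            pd.DataFrame(
                {
                    "pair_id": pd.Series(
                        [f"P{offset + i + 1:04d}" for i in range(n)], dtype="object"
                    ),
                    "zygosity": z,
                    "liab1_t1": y1[:, 0],
                    "liab2_t1": y1[:, 1],
                    "liab1_t2": y2[:, 0],
                    "liab2_t2": y2[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _sex_prevalences(prevalence, odds_ratio, p_male):
    """Per-sex non-right prevalences hitting the overall prevalence with the
    configured male:female odds ratio."""
    if odds_ratio == 1.0:
        return prevalence, prevalence

    def gap(p_f):
        odds_f = p_f / (1 - p_f)
        odds_m = odds_ratio * odds_f
        p_m = odds_m / (1 + odds_m)
        return p_male * p_m + (1 - p_male) * p_f - prevalence

    p_f = optimize.brentq(gap, 1e-6, 1 - 1e-6)
    odds_m = odds_ratio * p_f / (1 - p_f)
    return odds_m / (1 + odds_m), p_f


def liability_mean_shift(config: SimulationConfig, is_male: np.ndarray) -> np.ndarray:
    """Per-subject liability mean such that P(liability <= 0) matches the
    sex-specific non-right prevalence (liability is NRH when <= 0)."""
    p_m, p_f = _sex_prevalences(
        config.nrh_prevalence, config.male_nrh_odds_ratio, config.p_singleton_male
    )
    m_male = -stats.norm.ppf(p_m)
    m_female = -stats.norm.ppf(p_f)
    return np.where(is_male, m_male, m_female)


def simulate_binary(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    n_mz: Optional[int] = None,
    n_dz: Optional[int] = None,
    trait: int = 1,
) -> pd.DataFrame:
    """Binary twin records from thresholded liabilities (no sex structure).

    The trait is coded 1 when the standardized liability exceeds
    Phi^-1(prevalence), so the marginal frequency of the 0 class converges
    to the configured non-right prevalence, and the MZ/DZ tetrachoric
    correlations converge to a2 + c2 and 0.5 a2 + c2.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    liabs = simulate_pairs(config, rng=rng, n_mz=n_mz, n_dz=n_dz)
    tau = stats.norm.ppf(config.nrh_prevalence)
    out = liabs[["pair_id", "zygosity"]].copy()
    out["y_t1"] = (liabs[f"liab{trait}_t1"] > tau).astype(int)
    out["y_t2"] = (liabs[f"liab{trait}_t2"] > tau).astype(int)
    return out


def simulate_ehi_items(
    config: SimulationConfig,
    liabilities: np.ndarray,
    subject_ids,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Graded-response item answers for subjects with given preference
    liabilities (already shifted: zero is the right/non-right boundary).

    Each item's latent value is loading * liability + noise (unit total
    variance given a unit-variance liability); the five ordered categories
    are cut at -t2, -t1, t1, t2.
    """
    config.validate()
    liab = np.asarray(liabilities, dtype=float)
    rows = []
    for item in ITEMS:
        lam, t1, t2 = config.item_params[item]
        x = lam * liab + np.sqrt(1.0 - lam * lam) * rng.standard_normal(len(liab))
        hand = np.where(x < -t1, "left", np.where(x <= t1, "either", "right"))
        degree = np.where(np.abs(x) > t2, "always", "usually")
        degree = np.where(hand == "either", "", degree)
        rows.append(
            pd.DataFrame(
                {"subject_id": subject_ids, "item_id": item, "hand": hand, "degree": degree}
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_peg_trials(
    config: SimulationConfig,
    lateralities: np.ndarray,
    subject_ids,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-hand pegboard trials with laterality-linked asymmetry.

    Each subject has a base movement time and a true asymmetry
    q = pegq_mean + pegq_sd * laterality; per-hand trial times are the
    hand mean plus i.i.d. noise.  A configuration producing non-positive
    times raises rather than truncating.
    """
    config.validate()
    lat = np.asarray(lateralities, dtype=float)
    n = len(lat)
    base = config.peg_mean_time + config.peg_between_sd * rng.standard_normal(n)
    q = config.pegq_mean + config.pegq_sd * lat
    lmean = base * (1.0 + q / 2.0)
    rmean = base * (1.0 - q / 2.0)
    k = config.n_trials
    left = lmean[:, None] + config.peg_trial_sd * rng.standard_normal((n, k))
    right = rmean[:, None] + config.peg_trial_sd * rng.standard_normal((n, k))
    if left.min() <= 0 or right.min() <= 0:
        raise ValueError(
            "pegboard configuration produced a non-positive trial time; "
            "reduce noise or increase the mean time"
        )
    frames = []
    for hand, times in (("left", left), ("right", right)):
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(subject_ids, k),
                    "hand": hand,
                    "trial_index": np.tile(np.arange(1, k + 1), n),
                    "time_seconds": times.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _truncated_normal(rng, n, mean, sd, lo, hi):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _assign_twin_sexes(config, zygosity, rng):
    sex1, sex2 = [], []
    for z in zygosity:
        if z == "MZ":
            s = "male" if rng.random() < config.p_mz_male else "female"
            sex1.append(s)
            sex2.append(s)
        else:
            u = rng.random()
            mm, ff, _ = config.p_dz_mix
            if u < mm:
                sex1.append("male"); sex2.append("male")
            elif u < mm + ff:
                sex1.append("female"); sex2.append("female")
            else:
                first_male = rng.random() < 0.5
                sex1.append("male" if first_male else "female")
                sex2.append("female" if first_male else "male")
    return np.array(sex1), np.array(sex2)


def simulate_cohort(config: SimulationConfig, seed: Optional[int] = None) -> dict:
    """Full study bundle: roster, item responses and pegboard trials.

    Twin liabilities carry the ACE structure; singleton liabilities are
    independent draws with the same cross-trait correlation.  The male
    excess of non-right-handedness enters as a liability mean shift.
    Returns a dict of DataFrames (roster, items, pegs) plus the manifest.
    """
    config.validate()
    seed = config.seed if seed is None else seed
    rngs = _streams(seed, ["pairs", "singles", "sexes", "ages", "items", "pegs"])

    liabs = simulate_pairs(config, rng=rngs["pairs"])
    sex1, sex2 = _assign_twin_sexes(config, liabs["zygosity"], rngs["sexes"])
    m, s, lo, hi = config.twin_age
    twin_age = _truncated_normal(rngs["ages"], len(liabs), m, s, lo, hi).round(1)

    # per-subject twin table
    twins = []
    for j, (sex, suffix) in enumerate((( sex1, "a"), (sex2, "b")), start=1):
        twins.append(
            pd.DataFrame(
                {
                    "subject_id": liabs["pair_id"] + suffix,
                    "cohort": "twin",
                    "sex": sex,
                    "age": twin_age,
                    "pair_id": liabs["pair_id"],
                    "zygosity": liabs["zygosity"],
                    "pref_liab": liabs[f"liab1_t{j}"].to_numpy(),
                    "peg_liab": liabs[f"liab2_t{j}"].to_numpy(),
                }
            )
        )
    twins = pd.concat(twins, ignore_index=True)

    # singletons: same marginal structure, no pair correlation
    n_s = config.n_singletons
    rho = (
        config.r_a * np.sqrt(config.a2[0] * config.a2[1])
        + config.r_c * np.sqrt(config.c2[0] * config.c2[1])
        + config.r_e
        * np.sqrt((1 - config.a2[0] - config.c2[0]) * (1 - config.a2[1] - config.c2[1]))
    )
    z = _draw_factor(rngs["singles"], n_s, _factor_chol(float(rho)))
    sex_s = np.where(
        rngs["sexes"].random(n_s) < config.p_singleton_male, "male", "female"
    )
    m, s, lo, hi = config.singleton_age
    singles = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:04d}" for i in range(n_s)],
            "cohort": "singleton",
            "sex": sex_s,
            "age": _truncated_normal(rngs["ages"], n_s, m, s, lo, hi).round(1),
            "pair_id": "",
            "zygosity": "",
            "pref_liab": z[:, 0],
            "peg_liab": z[:, 1],
        }
    )

    roster = pd.concat([twins, singles], ignore_index=True)
    shift = liability_mean_shift(config, roster["sex"].to_numpy() == "male")
    pref = roster["pref_liab"].to_numpy() + shift

    items = simulate_ehi_items(config, pref, roster["subject_id"], rngs["items"])
    pegs = simulate_peg_trials(
        config, roster["peg_liab"].to_numpy(), roster["subject_id"], rngs["pegs"]
    )

    manifest = {
        "seed": seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
            if k != "item_params"
        },
        "item_params": {k: list(v) for k, v in config.item_params.items()},
    }
    roster = roster.drop(columns=["pref_liab", "peg_liab"])
    return {"roster": roster, "items": items, "pegs": pegs, "manifest": manifest}


def write_cohort(bundle: dict, outdir) -> dict:
    """Write the cohort bundle as UTF-8 CSVs plus a manifest JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("roster", "items", "pegs"):
        path = outdir / f"{name}.csv"
        bundle[name].to_csv(path, index=False, float_format="%.6f")
        paths[name] = str(path)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(bundle["manifest"], indent=2, sort_keys=True))
    paths["manifest"] = str(mpath)
    return paths
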