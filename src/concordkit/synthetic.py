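"""Synthetic linked EHR + census cohort generator with full ground truth.

The generator emulates the mechanisms that produce discordance and
missingness in real linked cohorts, so every pipeline stage is testable
without restricted microdata:

- a latent racial/ethnic identity per person (never Unreported), with the
  Multiracial mass split over explicit race-set combinations;
- practice-level recording defects: practices lacking a Hispanic option
  record latent-Hispanic patients under a fallback single race, practices
  lacking multi-select record latent-Multiracial patients as one component
  race chosen uniformly;
- per-category EHR nonreporting (masking to Unreported);
- *fluidity*: a per-person, time-invariant chance that the census-reported
  category differs from the latent one, via a confusion kernel whose mass
  moves preferentially between Hispanic and White, between a single race and
  a Multiracial set containing it (``AUGMENT``), and from Multiracial to one
  component (``COMPONENT``);
- 1–3 census observations per person with allocation flags and injected
  same-source-year conflicts;
- outcome ever-indicators drawn from per-person logits keyed to the latent
  category, and simple parametric covariates.

Because every branch is a finite mixture, :func:`expected_metrics` computes
the exact population values of every pipeline quantity (discordance,
missingness by group, group prevalences) by enumeration — the closed-form
oracle the recovery tests compare against.  Allocation and conflict drops
are independent of identity, so conditioning on cohort inclusion leaves
these expectations unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import Category, REPORTED_CATEGORIES, HarmonizedLabel, parse_label_token
from .concordance import Status, classify

__all__ = ["SyntheticConfig", "SyntheticBundle", "generate", "expected_metrics", "study_config"]

_CAT_NAMES = [c.value for c in REPORTED_CATEGORIES]

#: Display strings used in the raw EHR table (all present in the default
#: mapping fixture).
_EHR_RACE_STRING = {
    "White": "White",
    "Black": "Black or African American",
    "AIAN": "American Indian or Alaska Native",
    "Asian": "Asian",
    "NHPI": "Native Hawaiian or Other Pacific Islander",
}

AUGMENT = "AUGMENT"
COMPONENT = "COMPONENT"

DEFECT_NONE = "NONE"
DEFECT_NO_HISPANIC = "NO_HISPANIC_OPTION"
DEFECT_NO_MULTISELECT = "NO_MULTISELECT"

#: (code, system) pools per outcome group; all map back to the group through
#: the default crosswalk, exercising every coding system.
_CODE_POOLS: dict[str, list[tuple]] = {
    "E11": [("E11.9", "ICD10"), ("E11.65", "ICD10"), ("E11.42", "ICD10"),
            ("250.00", "ICD9"), ("44054006", "SNOMED")],
    "I10": [("I10", "ICD10"), ("401.9", "ICD9"), ("38341003", "SNOMED")],
    "J30": [("J30.9", "ICD10"), ("J30.1", "ICD10"), ("477.9", "ICD9")],
    "M54": [("M54.5", "ICD10"), ("724.2", "ICD9"), ("279039007", "SNOMED")],
    "Z00": [("Z00.00", "ICD10"), ("V70.0", "ICD9")],
}


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class SyntheticConfig:
    """Full generative parameterization.  See module docstring for semantics.

    ``confusion_kernel`` rows are per latent category; targets are category
    names, ``AUGMENT`` (single race r → Multiracial {r, partner}) or
    ``COMPONENT`` (Multiracial → one component, uniform).
    ``outcome_logits`` maps outcome group → (intercept, {category: offset})
    on the log-odds scale; a missing category offset is 0.
    """

    n_patients: int = 20_000
    n_practices: int = 200
    category_probs: dict = field(default_factory=dict)
    multiracial_sets: dict = field(default_factory=dict)
    ehr_missingness: dict = field(default_factory=dict)
    fluidity_rate: float = 0.05
    confusion_kernel: dict = field(default_factory=dict)
    augment_partner: dict = field(default_factory=dict)
    hispanic_fallback_race: str = "White"
    practice_defects: dict = field(default_factory=lambda: {DEFECT_NONE: 1.0})
    n_census_obs_probs: tuple = (0.35, 0.45, 0.20)
    p_decennial: float = 0.55
    allocation_rate: float = 0.04
    conflict_rate: float = 0.02
    decennial_years: tuple = (2000, 2010, 2020)
    acs_year_range: tuple = (2005, 2022)
    outcome_logits: dict = field(default_factory=dict)
    junk_event_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        from .census_resolution import ConfigurationError

        def _check_dist(d: Mapping, what: str) -> None:
            total = float(sum(d.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{what} must sum to 1 (got {total})")
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ConfigurationError(f"{what} has probabilities outside [0, 1]")

        _check_dist(self.category_probs, "category_probs")
        if self.category_probs.get("Multiracial", 0) > 0:
            _check_dist(self.multiracial_sets, "multiracial_sets")
        _check_dist(self.practice_defects, "practice_defects")
        _check_dist(dict(enumerate(self.n_census_obs_probs)), "n_census_obs_probs")
        for cat, row in self.confusion_kernel.items():
            _check_dist(row, f"confusion_kernel[{cat}]")
        for cat, m in self.ehr_missingness.items():
            if not 0 <= m <= 1:
                raise ConfigurationError(f"ehr_missingness[{cat}] outside [0, 1]")
        for r in (self.fluidity_rate, self.allocation_rate, self.conflict_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError("rates must lie in [0, 1]")
        if Category(self.hispanic_fallback_race) not in REPORTED_CATEGORIES:
            raise ConfigurationError("invalid hispanic_fallback_race")

    # -- enumeration helpers (shared by generate and expected_metrics) ------

    def latent_types(self) -> list:
        """[(token, category, prob)] over latent identities."""
        out = []
        for cat, p in self.category_probs.items():
            if cat == "Multiracial":
                for set_token, share in self.multiracial_sets.items():
                    races = "+".join(
                        sorted(set_token.split("+"), key=_CAT_NAMES.index)
                    )
                    out.append((f"Multiracial[{races}]", "Multiracial", p * share))
            elif p > 0:
                out.append((cat, cat, p))
        return out

    def defect_counts(self) -> dict:
        """Deterministic practice counts per defect type (largest remainder)."""
        fracs = {k: self.practice_defects.get(k, 0.0)
                 for k in (DEFECT_NO_HISPANIC, DEFECT_NO_MULTISELECT)}
        counts = {k: int(round(v * self.n_practices)) for k, v in fracs.items()}
        counts[DEFECT_NONE] = self.n_practices - sum(counts.values())
        if counts[DEFECT_NONE] < 0:
            raise ValueError("defect fractions exceed the practice count")
        return counts

    def census_options(self, token: str) -> list:
        """[(census_token, prob)] for a latent identity token."""
        lab = parse_label_token(token)
        cat = lab.category.value
        f = self.fluidity_rate
        out = [(token, 1.0 - f)]
        if f == 0:
            return out
        row = self.confusion_kernel.get(cat, {})
        if not row:  # no kernel row: fluid mass stays put
            out[0] = (token, 1.0)
            return out
        for target, w in row.items():
            if target == COMPONENT:
                comps = sorted(lab.race_set, key=lambda c: _CAT_NAMES.index(c.value))
                for comp in comps:
                    out.append((comp.value, f * w / len(comps)))
            elif target == AUGMENT:
                partner = self.augment_partner.get(cat, "White")
                pair = sorted({cat, partner}, key=_CAT_NAMES.index)
                out.append((f"Multiracial[{'+'.join(pair)}]", f * w))
            else:
                out.append((target, f * w))
        return out

    def ehr_options(self, token: str, defect: str) -> list:
        """[(ehr_token_pre_masking, prob)] for a latent identity + defect."""
        lab = parse_label_token(token)
        cat = lab.category.value
        if defect == DEFECT_NO_HISPANIC and cat == "Hispanic":
            return [(self.hispanic_fallback_race, 1.0)]
        if defect == DEFECT_NO_MULTISELECT and cat == "Multiracial":
            comps = sorted(lab.race_set, key=lambda c: _CAT_NAMES.index(c.value))
            return [(c.value, 1.0 / len(comps)) for c in comps]
        return [(token, 1.0)]

    def outcome_probs(self) -> pd.DataFrame:
        """Per latent-category outcome probabilities (categories x groups)."""
        data = {}
        for group, (intercept, offsets) in self.outcome_logits.items():
            data[group] = [
                float(_expit(intercept + offsets.get(cat, 0.0)))
                for cat in _CAT_NAMES
            ]
        return pd.DataFrame(data, index=_CAT_NAMES)


def expected_metrics(config: SyntheticConfig) -> dict:
    """Exact pipeline-quantity expectations by enumeration of the mixture.

    Returns overall missingness, per-census-group missingness, overall
    discordance with and without partial concordance counted as discordant,
    the expected partial share, and census-/EHR-labeled group prevalences
    for every configured outcome.  All conditional on cohort inclusion,
    which is identity-independent by construction.
    """
    config.validate()
    counts = config.defect_counts()
    p_defect = {k: v / config.n_practices for k, v in counts.items()}
    pout = config.outcome_probs()

    p_census_group = {c: 0.0 for c in _CAT_NAMES}
    miss_in_group = {c: 0.0 for c in _CAT_NAMES}
    out_census = {o: {c: 0.0 for c in _CAT_NAMES} for o in pout.columns}
    p_ehr_group = {c: 0.0 for c in _CAT_NAMES}
    out_ehr = {o: {c: 0.0 for c in _CAT_NAMES} for o in pout.columns}
    mass = {"reporting": 0.0, "strict_disc": 0.0, "partial": 0.0, "miss": 0.0}

    for latent_token, latent_cat, pi in config.latent_types():
        m = config.ehr_missingness.get(latent_cat, 0.0)
        py = {o: pout.loc[latent_cat, o] for o in pout.columns}
        census_opts = config.census_options(latent_token)
        for defect, pd_ in p_defect.items():
            if pd_ == 0:
                continue
            for ehr_token, pe in config.ehr_options(latent_token, defect):
                ehr_lab = parse_label_token(ehr_token)
                for census_token, pc in census_opts:
                    w = pi * pd_ * pe * pc
                    if w == 0:
                        continue
                    census_lab = parse_label_token(census_token)
                    ccat = census_lab.category.value
                    p_census_group[ccat] += w
                    miss_in_group[ccat] += w * m
                    mass["miss"] += w * m
                    for o in pout.columns:
                        out_census[o][ccat] += w * py[o]
                    w_rep = w * (1.0 - m)
                    mass["reporting"] += w_rep
                    ecat = ehr_lab.category.value
                    p_ehr_group[ecat] += w_rep
                    for o in pout.columns:
                        out_ehr[o][ecat] += w_rep * py[o]
                    status = classify(ehr_lab, census_lab, allow_partial=True)
                    if status is Status.DISCORDANT:
                        mass["strict_disc"] += w_rep
                    elif status is Status.PARTIAL:
                        mass["partial"] += w_rep

    rep = mass["reporting"]
    return {
        "overall_missingness": mass["miss"],
        "missingness_by_census_group": {
            c: miss_in_group[c] / p_census_group[c]
            for c in _CAT_NAMES
            if p_census_group[c] > 0
        },
        "overall_discordance_strict": (mass["strict_disc"] + mass["partial"]) / rep,
        "overall_discordance_partial": mass["strict_disc"] / rep,
        "partial_share": mass["partial"] / rep,
        "census_group_probs": p_census_group,
        "prevalence_census": {
            o: {
                c: out_census[o][c] / p_census_group[c]
                for c in _CAT_NAMES
                if p_census_group[c] > 0
            }
            for o in pout.columns
        },
        "prevalence_ehr": {
            o: {
                c: out_ehr[o][c] / p_ehr_group[c]
                for c in _CAT_NAMES
                if p_ehr_group[c] > 0
            }
            for o in pout.columns
        },
    }


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground truth the pipeline never reads."""

    ehr: pd.DataFrame
    census: pd.DataFrame
    events: pd.DataFrame
    covariates: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SyntheticConfig

    def write(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("ehr", "census", "events", "covariates", "ground_truth"):
            path = outdir / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            paths[name] = str(path)
        return paths


def _sample_from_options(options, n, rng):
    """Vector-sample token indices from an [(token, prob)] list."""
    tokens = [t for t, _ in options]
    probs = np.array([p for _, p in options], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(tokens), size=n, p=probs)
    return np.array(tokens, dtype=object)[idx]


def _token_to_census_fields(tokens: np.ndarray):
    """hispanic flag + semicolon race string per census label token."""
    hisp = tokens == "Hispanic"
    races = np.empty(len(tokens), dtype=object)
    cache: dict[str, str] = {}
    for t in np.unique(tokens):
        if t == "Hispanic":
            cache[t] = ""
        else:
            lab = parse_label_token(t)
            if lab.category is Category.MULTIRACIAL:
                cache[t] = ";".join(
                    sorted((c.value for c in lab.race_set), key=_CAT_NAMES.index)
                )
            else:
                cache[t] = lab.category.value
    for t, v in cache.items():
        races[tokens == t] = v
    return hisp.astype(int), races


def generate(config: SyntheticConfig, seed: int | None = None) -> SyntheticBundle:
    """Draw a full synthetic linked bundle.  Deterministic under (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    person = np.arange(n, dtype=np.int64)

    # latent identity
    types = config.latent_types()
    type_tokens = np.array([t for t, _, _ in types], dtype=object)
    type_cats = np.array([c for _, c, _ in types], dtype=object)
    type_probs = np.array([p for _, _, p in types], dtype=float)
    type_probs = type_probs / type_probs.sum()
    t_idx = rng.choice(len(types), size=n, p=type_probs)
    latent_token = type_tokens[t_idx]
    latent_cat = type_cats[t_idx]

    # practices and their defects
    counts = config.defect_counts()
    defect_by_practice = np.array(
        [DEFECT_NO_HISPANIC] * counts[DEFECT_NO_HISPANIC]
        + [DEFECT_NO_MULTISELECT] * counts[DEFECT_NO_MULTISELECT]
        + [DEFECT_NONE] * counts[DEFECT_NONE],
        dtype=object,
    )
    defect_by_practice = defect_by_practice[rng.permutation(config.n_practices)]
    practice = rng.integers(0, config.n_practices, size=n)
    defect = defect_by_practice[practice]

    # EHR recorded label (pre-masking), applying practice defects
    ehr_token = latent_token.copy()
    mask_h = (latent_cat == "Hispanic") & (defect == DEFECT_NO_HISPANIC)
    ehr_token[mask_h] = config.hispanic_fallback_race
    mask_m = (latent_cat == "Multiracial") & (defect == DEFECT_NO_MULTISELECT)
    for ti in np.unique(t_idx[mask_m]):
        rows = mask_m & (t_idx == ti)
        comps = sorted(
            parse_label_token(type_tokens[ti]).race_set,
            key=lambda c: _CAT_NAMES.index(c.value),
        )
        pick = rng.integers(0, len(comps), size=int(rows.sum()))
        ehr_token[rows] = np.array([c.value for c in comps], dtype=object)[pick]

    # nonreporting mask, per latent category
    m_prob = np.array(
        [config.ehr_missingness.get(c, 0.0) for c in latent_cat], dtype=float
    )
    missing = rng.random(n) < m_prob
    ehr_token_final = ehr_token.copy()
    ehr_token_final[missing] = "Unreported"

    # census-reported identity (per-person, time-invariant)
    census_token = np.empty(n, dtype=object)
    for ti in range(len(types)):
        rows = t_idx == ti
        k = int(rows.sum())
        if k == 0:
            continue
        census_token[rows] = _sample_from_options(
            config.census_options(type_tokens[ti]), k, rng
        )

    # --- EHR table (raw source strings) -----------------------------------
    eth = np.empty(n, dtype=object)
    rac = np.empty(n, dtype=object)
    for t in np.unique(ehr_token_final):
        rows = ehr_token_final == t
        if t == "Hispanic":
            eth[rows], rac[rows] = "Hispanic or Latino", ""
        elif t == "Unreported":
            eth[rows], rac[rows] = "", ""
        else:
            lab = parse_label_token(t)
            if lab.category is Category.MULTIRACIAL:
                rstr = ";".join(
                    _EHR_RACE_STRING[c.value]
                    for c in sorted(lab.race_set, key=lambda c: _CAT_NAMES.index(c.value))
                )
            else:
                rstr = _EHR_RACE_STRING[lab.category.value]
            eth[rows], rac[rows] = "Not Hispanic or Latino", rstr
    ehr = pd.DataFrame(
        {
            "person_key": person,
            "practice_key": practice,
            "ethnicity_code": eth,
            "race_codes": rac,
        }
    )

    # --- census observation table ------------------------------------------
    k_obs = rng.choice(
        [1, 2, 3], size=n, p=np.asarray(config.n_census_obs_probs, dtype=float)
    )
    rep_person = np.repeat(person, k_obs)
    rep_token = np.repeat(census_token, k_obs)
    n_rows = len(rep_person)
    is_dec = rng.random(n_rows) < config.p_decennial
    years = np.where(
        is_dec,
        rng.choice(np.asarray(config.decennial_years), size=n_rows),
        rng.integers(config.acs_year_range[0], config.acs_year_range[1] + 1, size=n_rows),
    )
    source = np.where(is_dec, "DECENNIAL", "ACS")
    allocated = (rng.random(n_rows) < config.allocation_rate).astype(int)
    hisp, races = _token_to_census_fields(rep_token)
    census = pd.DataFrame(
        {
            "person_key": rep_person,
            "source": source,
            "year": years,
            "allocated": allocated,
            "hispanic": hisp,
            "races": races,
        }
    )

    # injected same-source-year conflicts: duplicate the person's first
    # observation slot with two clashing labels — the resolver must drop the
    # whole (source, year) group
    conflict = rng.random(n) < config.conflict_rate
    if conflict.any():
        first_row = np.concatenate([[0], np.cumsum(k_obs)[:-1]])[conflict]
        true_tok = census_token[conflict]
        cat_idx = np.array(
            [_CAT_NAMES.index(parse_label_token(t).category.value) for t in true_tok]
        )
        shift_cat = np.array(_CAT_NAMES, dtype=object)[(cat_idx + 1) % len(_CAT_NAMES)]
        shift_tok = np.where(
            shift_cat == "Multiracial", "Multiracial[White+Black]", shift_cat
        ).astype(object)
        # normalize multiracial token ordering
        shift_tok[shift_tok == "Multiracial[White+Black]"] = "Multiracial[White+Black]"
        rows = []
        for tok in (true_tok, shift_tok):
            h, r = _token_to_census_fields(tok)
            rows.append(
                pd.DataFrame(
                    {
                        "person_key": person[conflict],
                        "source": source[first_row],
                        "year": years[first_row],
                        "allocated": 0,
                        "hispanic": h,
                        "races": r,
                    }
                )
            )
        census = pd.concat([census] + rows, ignore_index=True)

    # --- outcomes ------------------------------------------------------------
    pout = config.outcome_probs()
    y = {}
    cat_row = np.array([_CAT_NAMES.index(c) for c in latent_cat])
    for o in pout.columns:
        probs = pout[o].to_numpy()[cat_row]
        y[o] = (rng.random(n) < probs).astype(np.int8)
    event_frames = []
    for o in pout.columns:
        who = person[y[o] == 1]
        n_events = rng.integers(1, 3, size=len(who))
        ev_person = np.repeat(who, n_events)
        pool = _CODE_POOLS[o]
        pick = rng.integers(0, len(pool), size=len(ev_person))
        event_frames.append(
            pd.DataFrame(
                {
                    "person_key": ev_person,
                    "code": np.array([pool[i][0] for i in range(len(pool))], dtype=object)[pick],
                    "system": np.array([pool[i][1] for i in range(len(pool))], dtype=object)[pick],
                }
            )
        )
    events = pd.concat(event_frames, ignore_index=True)
    if config.junk_event_rate > 0:
        n_junk = int(round(config.junk_event_rate * len(events)))
        if n_junk:
            junk = pd.DataFrame(
                {
                    "person_key": rng.choice(person, size=n_junk),
                    "code": "999999999",
                    "system": "SNOMED",
                }
            )
            events = pd.concat([events, junk], ignore_index=True)
    events = events.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )

    # --- covariates ----------------------------------------------------------
    ref = pd.Timestamp("2021-12-31")
    age_days = rng.uniform(0, 90 * 365.25, size=n)
    dob = ref - pd.to_timedelta(age_days, unit="D")
    sex = rng.choice(["male", "female", "other"], size=n, p=[0.46, 0.525, 0.015])
    svi = rng.uniform(0, 100, size=n)
    svi[rng.random(n) < 0.07] = np.nan
    ruca_codes = np.arange(1, 11)
    ruca_w = np.array([0.35, 0.20, 0.13, 0.07, 0.05, 0.03, 0.05, 0.03, 0.02, 0.07])
    ruca = rng.choice(ruca_codes, size=n, p=ruca_w / ruca_w.sum()).astype(float)
    ruca[rng.random(n) < 0.07] = np.nan
    covariates = pd.DataFrame(
        {
            "person_key": person,
            "dob": dob.normalize(),
            "sex": sex,
            "svi_score": svi,
            "ruca_code": ruca,
            "practice_key": practice,
        }
    )

    ground_truth = pd.DataFrame(
        {
            "person_key": person,
            "latent_category": latent_cat,
            "latent_label": latent_token,
            "practice_defect": defect,
            "ehr_missing": missing.astype(int),
            "census_label": census_token,
            **{f"y_{o}": y[o] for o in pout.columns},
            **{f"p_{o}": pout[o].to_numpy()[cat_row] for o in pout.columns},
        }
    )

    return SyntheticBundle(ehr, census, events, covariates, ground_truth, config)


def study_config(n_patients: int = 100_000, seed: int = 0) -> SyntheticConfig:
    """The study-condition configuration.

    Constants are set so the generator's *closed-form* expectations (via
    :func:`expected_metrics`, not simulation) land at the magnitudes the
    linked-cohort literature reports for primary-care EHR populations:
    overall strict discordance ≈ 8.0% dropping to ≈ 5.4% when partial
    concordance is allowed, overall EHR missingness ≈ 19.3% ranging from
    ≈ 17.7% (White) to ≈ 35.2% / 39.1% (Asian / NHPI), and census-labeled
    Type 2 diabetes (E11) prevalence ≈ 17.0% for NHPI vs ≈ 11.5% for White.
    """

    def _logits(p_by_cat: dict) -> tuple:
        base = float(np.log(p_by_cat["White"] / (1 - p_by_cat["White"])))
        offsets = {
            c: float(np.log(p / (1 - p))) - base for c, p in p_by_cat.items()
        }
        return base, offsets

    outcome_logits = {
        # Type 2 diabetes analog: NHPI highest, White lowest
        "E11": _logits({"Hispanic": 0.145, "White": 0.115, "Black": 0.155,
                        "AIAN": 0.16, "Asian": 0.12, "NHPI": 0.18,
                        "Multiracial": 0.13}),
        # hypertension analog
        "I10": _logits({"Hispanic": 0.28, "White": 0.30, "Black": 0.38,
                        "AIAN": 0.32, "Asian": 0.25, "NHPI": 0.33,
                        "Multiracial": 0.28}),
        # allergic rhinitis analog: NHPI highest -> census relabeling lowers it
        "J30": _logits({"Hispanic": 0.12, "White": 0.12, "Black": 0.11,
                        "AIAN": 0.12, "Asian": 0.13, "NHPI": 0.22,
                        "Multiracial": 0.13}),
        # low back pain analog, nearly flat
        "M54": _logits({"Hispanic": 0.18, "White": 0.18, "Black": 0.17,
                        "AIAN": 0.19, "Asian": 0.15, "NHPI": 0.18,
                        "Multiracial": 0.18}),
        # general-exam administrative code (excluded from outcome rankings)
        "Z00": _logits({"Hispanic": 0.22, "White": 0.26, "Black": 0.24,
                        "AIAN": 0.22, "Asian": 0.28, "NHPI": 0.24,
                        "Multiracial": 0.25}),
    }

    return SyntheticConfig(
        n_patients=n_patients,
        n_practices=1290,
        category_probs={
            "Hispanic": 0.120, "White": 0.729, "Black": 0.080, "AIAN": 0.008,
            "Asian": 0.032, "NHPI": 0.0012, "Multiracial": 0.0298,
        },
        multiracial_sets={
            "White+Black": 0.40, "White+AIAN": 0.25, "White+Asian": 0.20,
            "White+NHPI": 0.05, "Black+AIAN": 0.05, "Black+Asian": 0.05,
        },
        ehr_missingness={
            "Hispanic": 0.21, "White": 0.177, "Black": 0.20, "AIAN": 0.30,
            "Asian": 0.372, "NHPI": 0.397, "Multiracial": 0.30,
        },
        fluidity_rate=0.05,
        confusion_kernel={
            "Hispanic": {"White": 0.70, "Black": 0.15, "Asian": 0.10, "AIAN": 0.05},
            "White": {"Hispanic": 0.45, AUGMENT: 0.30, "AIAN": 0.10,
                      "Black": 0.08, "Asian": 0.07},
            "Black": {AUGMENT: 0.50, "Hispanic": 0.25, "White": 0.25},
            "AIAN": {"White": 0.50, AUGMENT: 0.35, "Hispanic": 0.15},
            "Asian": {AUGMENT: 0.45, "White": 0.30, "NHPI": 0.15, "Hispanic": 0.10},
            "NHPI": {AUGMENT: 0.40, "White": 0.30, "Asian": 0.30},
            "Multiracial": {COMPONENT: 1.0},
        },
        augment_partner={"White": "Black", "Black": "White", "AIAN": "White",
                         "Asian": "White", "NHPI": "White"},
        practice_defects={
            DEFECT_NO_HISPANIC: 0.17, DEFECT_NO_MULTISELECT: 0.49,
            DEFECT_NONE: 0.34,
        },
        outcome_logits=outcome_logits,
        seed=seed,
    )
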