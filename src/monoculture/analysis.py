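"""The meta-analytic model battery, bias diagnostics and relevance scoring.

Each analysis fits the BPMM with a single categorical moderator whose
levels are a cross of study characteristics, coded *without* a global
intercept (one coefficient per level).  Level posteriors and pairwise
contrasts are then direct linear combinations of the fixed-effect
draws: a contrast between two levels is simply the per-draw difference
of their coefficients.

The battery mirrors the structure of the evidence base:

* ``m1_intercept`` — overall mean effect of relatedness.
* ``m2_fitness_measure`` — three levels: mortality with pathogens
  present, mortality with pathogens absent, pathogen abundance.
* ``m3_pathogen_by_studytype`` — pathogen presence/absence crossed with
  experimental vs observational pathogen manipulation (four levels).
* ``m4_relmanip_by_pathogen`` — pathogen presence/absence crossed with
  experimental vs observational *relatedness* manipulation; this is the
  "full model" used for the bias diagnostics and verification refits.
* ``m5_kin_by_pathogen_by_studytype`` — kin/non-kin crossed with
  pathogen presence and manipulation (eight levels; empty cells are
  reported as unavailable rather than silently dropped).
* ``m6_lncvr_variants`` — the m1–m4 structures refitted on the LnCVR
  (variance-ratio) effect sizes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bpmm import ChainConfig, PROFILES, PhyloMetaRegression
from .posterior import PosteriorSummary, hpd_interval, pmcmc, posterior_mode

__all__ = [
    "AnalysisPlan",
    "AnalysisResult",
    "PLANS",
    "KeywordScheme",
    "DEFAULT_KEYWORD_SCHEME",
    "build_design",
    "run_analysis",
    "run_suite",
    "eggers_test",
    "funnel_data",
    "verification_refits",
    "relevance_score",
]

LEVEL_SEP = "|"


@dataclass(frozen=True)
class AnalysisPlan:
    """One model of the battery: response plus the moderator cross."""

    analysis_id: str
    response: str                    # "Zr" | "LnCVR"
    factors: tuple[str, ...] = ()    # () -> intercept-only


PLANS: dict[str, AnalysisPlan] = {
    p.analysis_id: p
    for p in [
        AnalysisPlan("m1_intercept", "Zr"),
        AnalysisPlan("m2_fitness_measure", "Zr", ("fitness_measure",)),
        AnalysisPlan("m3_pathogen_by_studytype", "Zr",
                     ("pathogen_presence", "pathogen_manipulated")),
        AnalysisPlan("m4_relmanip_by_pathogen", "Zr",
                     ("pathogen_presence", "relatedness_manipulated")),
        AnalysisPlan("m5_kin_by_pathogen_by_studytype", "Zr",
                     ("kin_structure", "pathogen_presence",
                      "pathogen_manipulated")),
        AnalysisPlan("m6_lncvr_intercept", "LnCVR"),
        AnalysisPlan("m6_lncvr_fitness_measure", "LnCVR", ("fitness_measure",)),
        AnalysisPlan("m6_lncvr_pathogen_by_studytype", "LnCVR",
                     ("pathogen_presence", "pathogen_manipulated")),
        AnalysisPlan("m6_lncvr_relmanip_by_pathogen", "LnCVR",
                     ("pathogen_presence", "relatedness_manipulated")),
    ]
}

#: the ids run by :func:`run_suite`; ``m6_lncvr_variants`` expands to
#: the LnCVR refits of analyses 1-4 (variance data are too sparse for
#: the eight-level kin model)
M6_VARIANTS = (
    "m6_lncvr_intercept",
    "m6_lncvr_fitness_measure",
    "m6_lncvr_pathogen_by_studytype",
    "m6_lncvr_relmanip_by_pathogen",
)
SUITE_IDS = (
    "m1_intercept",
    "m2_fitness_measure",
    "m3_pathogen_by_studytype",
    "m4_relmanip_by_pathogen",
    "m5_kin_by_pathogen_by_studytype",
) + M6_VARIANTS


def _with_fitness_measure(records: pd.DataFrame) -> pd.DataFrame:
    out = records.copy()
    out["fitness_measure"] = np.where(
        out["measure"] == "pathogen_abundance",
        "pathogen_abundance",
        np.where(out["pathogen_presence"] == "present",
                 "mortality_present", "mortality_absent"),
    )
    return out


def build_design(
    records: pd.DataFrame, plan: AnalysisPlan
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """Subset records to the plan's response and build its design matrix.

    Returns ``(subset, design, observed_levels, expected_levels)``.
    Factor models are coded one indicator column per observed level (no
    global intercept).  ``expected_levels`` is the full cross of the
    per-factor level sets seen in the data, so callers can detect empty
    cells.
    """
    sub = records[records["effect_type"] == plan.response].copy()
    if sub.empty:
        raise ValueError(f"no records with effect_type {plan.response!r}")
    if not plan.factors:
        design = pd.DataFrame({"intercept": np.ones(len(sub))}, index=sub.index)
        return sub, design, ["intercept"], ["intercept"]
    if "fitness_measure" in plan.factors:
        sub = _with_fitness_measure(sub)
    for f in plan.factors:
        if sub[f].isna().any():
            raise ValueError(f"moderator column {f!r} has missing values")
    combo = sub[list(plan.factors)].astype(str).agg(LEVEL_SEP.join, axis=1)
    observed = sorted(combo.unique())
    per_factor = [sorted(sub[f].astype(str).unique()) for f in plan.factors]
    expected = observed
    if len(plan.factors) > 1:
        grids = np.meshgrid(*per_factor, indexing="ij")
        expected = sorted(
            LEVEL_SEP.join(vals)
            for vals in zip(*(g.ravel() for g in grids))
        )
    design = pd.DataFrame(
        {lvl: (combo == lvl).astype(float) for lvl in observed}, index=sub.index
    )
    return sub, design, observed, expected


@dataclass
class AnalysisResult:
    """Fitted model plus tidy level and contrast tables."""

    plan: AnalysisPlan
    model: PhyloMetaRegression
    levels: pd.DataFrame      # one row per (available) factor level
    contrasts: pd.DataFrame   # one row per ordered level pair
    design_columns: list[str] = field(default_factory=list)

    def level_draws(self, level: str) -> np.ndarray:
        return self.model.coef_draws(level)

    def contrast_draws(self, level_a: str, level_b: str) -> np.ndarray:
        """Per-draw difference ``level_a - level_b``."""
        return self.level_draws(level_a) - self.level_draws(level_b)


def _summary_row(draws: np.ndarray) -> dict:
    lo, hi = hpd_interval(draws)
    return {
        "pm": posterior_mode(draws),
        "ci_low": lo,
        "ci_high": hi,
        "pmcmc": pmcmc(draws),
    }


def run_analysis(
    records: pd.DataFrame,
    corr: pd.DataFrame,
    plan: AnalysisPlan | str,
    *,
    profile: str | ChainConfig = "desk",
    seed=None,
    random_terms: Sequence[str] = ("study", "species", "phylo"),
    extra_random: Mapping[str, Sequence] | None = None,
    **model_kwargs,
) -> AnalysisResult:
    """Fit one analysis of the battery and summarise levels + contrasts.

    Every pairwise contrast between factor levels is computed per draw
    as the coefficient difference; a contrast touching an empty factor
    cell is reported with ``available = False`` instead of being
    dropped.
    """
    if isinstance(plan, str):
        plan = PLANS[plan]
    cfg = PROFILES[profile] if isinstance(profile, str) else profile
    sub, design, observed, expected = build_design(records, plan)
    model = PhyloMetaRegression(
        random_terms=random_terms,
        iterations=cfg.iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        n_chains=cfg.n_chains,
        random_state=seed,
        **model_kwargs,
    )
    if extra_random is not None:
        pos = records.index.get_indexer(sub.index)
        extra_random = {
            k: np.asarray(v)[pos] if len(v) == len(records) else np.asarray(v)
            for k, v in extra_random.items()
        }
    model.fit(
        design,
        sub["value"],
        sub["sampling_variance"],
        study=sub["study_id"],
        species=sub["species_id"],
        phylo_corr=corr,
        extra_random=extra_random,
    )

    level_rows = []
    for lvl in expected:
        if lvl in observed:
            row = {"level": lvl, "available": True,
                   **_summary_row(model.coef_draws(lvl))}
        else:
            row = {"level": lvl, "available": False, "pm": np.nan,
                   "ci_low": np.nan, "ci_high": np.nan, "pmcmc": np.nan}
        level_rows.append(row)

    contrast_rows = []
    for i, la in enumerate(expected):
        for lb in expected[i + 1 :]:
            if la in observed and lb in observed:
                draws = model.coef_draws(la) - model.coef_draws(lb)
                row = {"level_a": la, "level_b": lb, "available": True,
                       **_summary_row(draws)}
            else:
                row = {"level_a": la, "level_b": lb, "available": False,
                       "pm": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                       "pmcmc": np.nan}
            contrast_rows.append(row)

    return AnalysisResult(
        plan=plan,
        model=model,
        levels=pd.DataFrame(level_rows),
        contrasts=pd.DataFrame(contrast_rows),
        design_columns=observed,
    )


def run_suite(
    records: pd.DataFrame,
    corr: pd.DataFrame,
    *,
    profile: str | ChainConfig = "desk",
    seed=None,
    analysis_ids: Sequence[str] = SUITE_IDS,
) -> dict[str, AnalysisResult | str]:
    """Run the full battery with per-analysis seeds spawned from one seed.

    Analyses whose response has no records (e.g. LnCVR refits on a
    Zr-only table) are reported as ``"unavailable"``.
    """
    streams = np.random.SeedSequence(seed).spawn(len(analysis_ids))
    results: dict[str, AnalysisResult | str] = {}
    for aid, ss in zip(analysis_ids, streams):
        try:
            results[aid] = run_analysis(
                records, corr, PLANS[aid], profile=profile, seed=ss
            )
        except ValueError:
            results[aid] = "unavailable"
    return results


def eggers_test(
    records: pd.DataFrame,
    corr: pd.DataFrame,
    base_plan: AnalysisPlan | str = "m4_relmanip_by_pathogen",
    *,
    profile: str | ChainConfig = "desk",
    seed=None,
    **model_kwargs,
) -> tuple[PosteriorSummary, AnalysisResult]:
    """Egger-style publication-bias test on the full model.

    Refits the base model with the (mean-centred) inverse sampling
    variance ``1/v_i`` added as a continuous covariate.  A slope whose
    credible interval excludes zero indicates funnel asymmetry
    (small-study / publication bias); an interval spanning zero is the
    no-bias conclusion.  Centring only shifts the level coefficients,
    not the slope.
    """
    if isinstance(base_plan, str):
        base_plan = PLANS[base_plan]
    cfg = PROFILES[profile] if isinstance(profile, str) else profile
    sub, design, observed, expected = build_design(records, base_plan)
    w = 1.0 / sub["sampling_variance"].to_numpy(dtype=float)
    if np.ptp(w) == 0:
        raise ValueError("inverse sampling variance is constant; "
                         "Egger covariate is degenerate")
    design = design.copy()
    design["inv_sampling_variance"] = w - w.mean()
    model = PhyloMetaRegression(
        iterations=cfg.iterations,
        burn_in=cfg.burn_in,
        thin=cfg.thin,
        n_chains=cfg.n_chains,
        random_state=seed,
        **model_kwargs,
    )
    model.fit(
        design,
        sub["value"],
        sub["sampling_variance"],
        study=sub["study_id"],
        species=sub["species_id"],
        phylo_corr=corr,
    )
    draws = model.coef_draws("inv_sampling_variance")
    slope = PosteriorSummary(**_summary_row(draws))
    result = AnalysisResult(
        plan=base_plan, model=model, levels=pd.DataFrame(),
        contrasts=pd.DataFrame(), design_columns=list(design.columns),
    )
    return slope, result


def funnel_data(
    records: pd.DataFrame, result: AnalysisResult
) -> pd.DataFrame:
    """Meta-analytic residuals vs precision, ready for a funnel plot.

    One row per retained record: ``residual`` is the effect size minus
    the fixed-effect (marginal) prediction at the posterior mean, and
    ``precision`` is ``1/sqrt(v_i)``.  Export only — no plotting here.
    """
    sub, design, _, _ = build_design(records, result.plan)
    design = design.reindex(columns=result.model.coef_names_, fill_value=0.0)
    resid = sub["value"].to_numpy(dtype=float) - result.model.predict(design)
    return pd.DataFrame({
        "study_id": sub["study_id"].to_numpy(),
        "species_id": sub["species_id"].to_numpy(),
        "residual": resid,
        "precision": 1.0 / np.sqrt(sub["sampling_variance"].to_numpy(dtype=float)),
    })


def verification_refits(
    records: pd.DataFrame,
    corr: pd.DataFrame,
    *,
    profile: str | ChainConfig = "desk",
    seed=None,
) -> dict[str, AnalysisResult | str]:
    """Robustness refits of the full (m4) model.

    (a) ``no_inbreeding`` — drop records where inbreeding was possible;
    (b) ``lab_vs_field`` — observational-pathogen records only, with
    the lab/field setting crossed into the moderator; (c)
    ``technique_random`` — the m4 model with the reported analysis
    technique as an extra iid random term.  A refit whose subset is
    emptied by filtering is reported as ``"unavailable"``.
    """
    streams = np.random.SeedSequence(seed).spawn(3)
    out: dict[str, AnalysisResult | str] = {}

    no_inbred = records[~records["inbreeding_possible"].astype(bool)]
    try:
        out["no_inbreeding"] = run_analysis(
            no_inbred, corr, "m4_relmanip_by_pathogen",
            profile=profile, seed=streams[0],
        )
    except (ValueError, KeyError):
        out["no_inbreeding"] = "unavailable"

    observational = records[records["pathogen_manipulated"] == "observational"]
    lab_field_plan = AnalysisPlan(
        "verification_lab_vs_field", "Zr", ("pathogen_presence", "setting")
    )
    if observational.empty or observational[
        observational["effect_type"] == "Zr"
    ].empty:
        out["lab_vs_field"] = "unavailable"
    else:
        out["lab_vs_field"] = run_analysis(
            observational, corr, lab_field_plan,
            profile=profile, seed=streams[1],
        )

    try:
        out["technique_random"] = run_analysis(
            records, corr, "m4_relmanip_by_pathogen",
            profile=profile, seed=streams[2],
            random_terms=("study", "species", "phylo", "analysis_technique"),
            extra_random={
                "analysis_technique": records["analysis_technique"].to_numpy()
            },
        )
    except ValueError:
        out["technique_random"] = "unavailable"
    return out


# ----------------------------------------------------------------------
# literature relevance scoring


@dataclass(frozen=True)
class KeywordScheme:
    """Positive/negative keyword lists with per-word weights."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"words in both lists: {sorted(overlap)}")
        for w, val in self.weights.items():
            if not np.isfinite(val):
                raise ValueError(f"non-finite weight for {w!r}")

    def weight(self, word: str) -> float:
        return float(self.weights.get(word, 1.0))


#: the screening vocabulary: terms about group genetic composition and
#: disease outcomes score positively; biomedical/clinical terms flag
#: off-topic abstracts
DEFAULT_KEYWORD_SCHEME = KeywordScheme(
    positive=(
        "genetic", "diversity", "diversities", "variation", "relatedness",
        "related", "unrelatedness", "unrelated", "diverse", "parasite",
        "ectoparasite", "ectoparasites", "parasites", "pathogen",
        "pathogenic", "pathogens", "disease", "diseases", "diseased",
        "mortality", "survival", "resistance", "infection", "infections",
        "prevalence", "tolerance", "transmission", "population", "group",
        "colony", "groups", "colonies", "populations",
    ),
    negative=("human", "humans", "hospital", "cancer", "hiv", "patients"),
)

_WORD_RE = re.compile(r"[a-z]+")


def relevance_score(
    abstract_text: str, scheme: KeywordScheme = DEFAULT_KEYWORD_SCHEME
) -> float:
    """Keyword relevance score of an abstract.

    Lowercase word-frequency count: each occurrence of a positive word
    adds its weight, each occurrence of a negative word subtracts its
    weight (default weight 1).  Linear in the text, so duplicating an
    abstract doubles its score.
    """
    if not abstract_text:
        raise ValueError("abstract text is empty")
    counts: dict[str, int] = {}
    for w in _WORD_RE.findall(abstract_text.lower()):
        counts[w] = counts.get(w, 0) + 1
    score = sum(counts.get(w, 0) * scheme.weight(w) for w in scheme.positive)
    score -= sum(counts.get(w, 0) * scheme.weight(w) for w in scheme.negative)
    return float(score)
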