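"""Synthetic datasets with the structure the meta-analysis assumes.

The generator mirrors the shape of the real evidence base: a few dozen
species on a taxonomy-derived tree, one or more studies per species,
one to six effect sizes per study, per-effect sampling variances driven
by the number of groups studied, and categorical moderators with known
true contrasts.  Because the truth is known, every stage of the
pipeline — effect-size construction, tree building, the meta-regression
and the bias diagnostics — can be scored for recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .phylo import grafen_lengths, phylo_correlation, tree_from_taxonomy

__all__ = [
    "SyntheticTruth",
    "RawStudySim",
    "SelectionRule",
    "random_taxonomy",
    "simulate_effect_table",
    "simulate_raw_groups",
    "summarize_arms",
    "apply_selection_bias",
]

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: analysis-technique labels sampled at study level (the evidence base
#: mixes ~15 different statistical approaches)
TECHNIQUES = tuple(f"technique_{i:02d}" for i in range(15))


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters for one synthetic effect-size table.

    ``factors`` name the moderator columns whose crossed levels carry
    the true fixed effects; ``level_means`` maps each level combination
    to its true mean Zr.  The default truth encodes the headline
    pattern of interest: under experimental pathogen manipulation the
    absent-vs-present contrast is -0.4 (absent -0.2, present +0.2),
    while observational effects sit near zero.  All four variance
    components default to 0.05.
    """

    factors: tuple[str, ...] = ("pathogen_presence", "pathogen_manipulated")
    level_means: dict = field(
        default_factory=lambda: {
            ("absent", "experimental"): -0.2,
            ("present", "experimental"): 0.2,
            ("absent", "observational"): 0.05,
            ("present", "observational"): 0.05,
        }
    )
    lncvr_level_means: dict | None = None  # defaults to all-zero
    s2_study: float = 0.05
    s2_species: float = 0.05
    s2_phylo: float = 0.05
    s2_residual: float = 0.05
    n_species: int = 56
    n_studies: int = 75
    n_effects: int = 210
    n_lncvr: int = 106
    max_effects_per_study: int = 6
    kin_imbalance: bool = False  # True -> the observed 41 kin / 15 non-kin split

    def __post_init__(self) -> None:
        for v in (self.s2_study, self.s2_species, self.s2_phylo, self.s2_residual):
            if v < 0:
                raise ValueError("variance components must be non-negative")
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.n_studies < self.n_species:
            raise ValueError("need at least one study per species")
        if not self.n_studies <= self.n_effects <= (
            self.n_studies * self.max_effects_per_study
        ):
            raise ValueError("n_effects incompatible with per-study limits")


def random_taxonomy(
    n_species: int, seed=None, n_ranks: int = len(RANKS)
) -> pd.DataFrame:
    """Random ranked-lineage table with nested clades of varying size.

    Species are partitioned recursively: at each rank every block of
    species splits into one to three named subclades, so the implied
    topology mixes cherries, larger clades and polytomies the way a
    real taxonomy does.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i:03d}" for i in range(n_species)]
    rows = np.zeros((n_species, n_ranks), dtype=object)
    rows[:, -1] = species
    blocks = [np.arange(n_species)]
    counter = 0
    for depth in range(n_ranks - 1):
        rank = RANKS[depth] if n_ranks == len(RANKS) else f"rank{depth + 1}"
        new_blocks = []
        for block in blocks:
            n_split = 1 if len(block) == 1 else int(rng.integers(1, 4))
            n_split = min(n_split, len(block))
            shuffled = rng.permutation(block)
            cuts = np.sort(rng.choice(
                np.arange(1, len(block)), size=n_split - 1, replace=False
            )) if n_split > 1 else np.array([], dtype=int)
            for part in np.split(shuffled, cuts):
                name = f"{rank[:3]}{counter:03d}"
                counter += 1
                rows[part, depth] = name
                new_blocks.append(part)
        blocks = new_blocks
    colnames = list(RANKS) if n_ranks == len(RANKS) else [
        f"rank{i + 1}" for i in range(n_ranks - 1)
    ] + ["species"]
    df = pd.DataFrame(rows, columns=colnames)
    df.iloc[:, -1] = species
    return df


def _corr_from_tree_arg(tree_or_S, rng) -> pd.DataFrame:
    if isinstance(tree_or_S, pd.DataFrame):
        return tree_or_S
    if isinstance(tree_or_S, dendropy.Tree):
        return phylo_correlation(tree_or_S)
    S = int(tree_or_S)
    tax = random_taxonomy(S, seed=rng)
    return phylo_correlation(grafen_lengths(tree_from_taxonomy(tax)))


def _draw_n_groups(rng, size):
    # shifted negative binomial: minimum 4, mode ~10 — over 93% of the
    # underlying studies used groups of five or more individuals, and
    # group counts in this range give a realistic spread of 1/(n-3)
    return 4 + rng.negative_binomial(5, 0.4, size=size)


def simulate_effect_table(
    truth: SyntheticTruth,
    tree_or_S=None,
    seed=None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate an effect-size table with known ground truth.

    ``tree_or_S`` may be a species correlation matrix (DataFrame), a
    tree with branch lengths, or a species count (a random taxonomy is
    then built); ``None`` uses ``truth.n_species``.

    Returns ``(records, corr, info)`` where ``info`` echoes the truth
    and the realised random effects for recovery scoring.
    """
    rng = np.random.default_rng(seed)
    if tree_or_S is None:
        tree_or_S = truth.n_species
    corr = _corr_from_tree_arg(tree_or_S, rng)
    species = list(corr.index)
    S = len(species)
    if S < 4:
        raise ValueError("need at least 4 species")
    if truth.s2_phylo > 0 and corr is None:
        raise ValueError("phylogenetic variance requires a tree")

    # species-level random effects
    A = corr.to_numpy(dtype=float)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(S))
    u_phylo = math.sqrt(truth.s2_phylo) * (L @ rng.standard_normal(S))
    u_species = math.sqrt(truth.s2_species) * rng.standard_normal(S)

    # studies: every species gets one, the surplus lands at random
    study_species = np.concatenate([
        rng.permutation(S),
        rng.integers(0, S, size=truth.n_studies - S),
    ]) if truth.n_studies > S else rng.permutation(S)[: truth.n_studies]
    u_study = math.sqrt(truth.s2_study) * rng.standard_normal(truth.n_studies)

    # effects per study: at least one each, 1..max per study
    per_study = np.ones(truth.n_studies, dtype=int)
    surplus = truth.n_effects - truth.n_studies
    while surplus > 0:
        j = int(rng.integers(truth.n_studies))
        if per_study[j] < truth.max_effects_per_study:
            per_study[j] += 1
            surplus -= 1

    # species-level kin classification
    if truth.kin_imbalance:
        n_kin = round(S * 41 / 56)
    else:
        n_kin = S // 2
    kin_species = set(rng.permutation(S)[:n_kin])

    level_keys = list(truth.level_means)
    study_rows = []
    for j in range(truth.n_studies):
        study_rows.append({
            "study_id": f"study{j:03d}",
            "species_i": int(study_species[j]),
            "relatedness_manipulated": ("experimental", "observational")[j % 2],
            "inbreeding_possible": bool(rng.random() < 0.15),
            "analysis_technique": TECHNIQUES[int(rng.integers(len(TECHNIQUES)))],
        })

    records = []
    effect_counter = 0
    for j, srow in enumerate(study_rows):
        for _ in range(per_study[j]):
            key = level_keys[effect_counter % len(level_keys)]
            mods = dict(zip(truth.factors, key))
            presence = mods.get("pathogen_presence",
                                ("present", "absent")[effect_counter % 2])
            manipulated = mods.get("pathogen_manipulated",
                                   ("experimental", "observational")[j % 2])
            if presence == "present" and effect_counter % 3 == 0:
                measure = "pathogen_abundance"
            else:
                measure = "mortality"
            measure = mods.get("measure", measure)
            setting = "lab" if manipulated == "experimental" else (
                "field" if rng.random() < 0.86 else "lab"
            )
            n_groups = int(_draw_n_groups(rng, 1)[0])
            v = 1.0 / (n_groups - 3)
            si = srow["species_i"]
            mu = truth.level_means[key]
            y = (
                mu
                + u_study[j]
                + u_species[si]
                + u_phylo[si]
                + math.sqrt(truth.s2_residual) * rng.standard_normal()
                + math.sqrt(v) * rng.standard_normal()
            )
            records.append({
                "study_id": srow["study_id"],
                "species_id": species[si],
                "effect_type": "Zr",
                "value": y,
                "sampling_variance": v,
                "n_groups": n_groups,
                "pathogen_presence": presence,
                "measure": measure,
                "pathogen_manipulated": manipulated,
                "relatedness_manipulated": srow["relatedness_manipulated"],
                "kin_structure": "kin" if si in kin_species else "non_kin",
                "setting": setting,
                "inbreeding_possible": srow["inbreeding_possible"],
                "analysis_technique": srow["analysis_technique"],
                "sign_flipped": False,
            })
            effect_counter += 1

    table = pd.DataFrame(records)

    # LnCVR companions for a subset of effects, with their own
    # random-effect draws (the variance response is a different quantity)
    lncvr_means = truth.lncvr_level_means or {k: 0.0 for k in level_keys}
    u_phylo_v = math.sqrt(truth.s2_phylo) * (L @ rng.standard_normal(S))
    u_species_v = math.sqrt(truth.s2_species) * rng.standard_normal(S)
    u_study_v = math.sqrt(truth.s2_study) * rng.standard_normal(truth.n_studies)
    n_lncvr = min(truth.n_lncvr, len(table))
    companion_idx = rng.permutation(len(table))[:n_lncvr]
    lrecords = []
    study_index = {s["study_id"]: j for j, s in enumerate(study_rows)}
    for i in sorted(companion_idx):
        row = table.iloc[i]
        key = tuple(row[f] for f in truth.factors)
        n_arm = max(2, row["n_groups"] // 2)
        cv = 0.3
        v_l = 2 * (cv**2 / n_arm + 1.0 / (2 * (n_arm - 1)))
        j = study_index[row["study_id"]]
        si = species.index(row["species_id"])
        y = (
            lncvr_means[key]
            + u_study_v[j]
            + u_species_v[si]
            + u_phylo_v[si]
            + math.sqrt(truth.s2_residual) * rng.standard_normal()
            + math.sqrt(v_l) * rng.standard_normal()
        )
        rec = row.to_dict()
        rec.update(effect_type="LnCVR", value=y, sampling_variance=v_l)
        lrecords.append(rec)
    if lrecords:
        table = pd.concat([table, pd.DataFrame(lrecords)], ignore_index=True)

    info = {
        "truth": truth,
        "u_study": u_study,
        "u_species": u_species,
        "u_phylo": u_phylo,
        "species": species,
    }
    return table, corr, info


@dataclass(frozen=True)
class RawStudySim:
    """Generator settings for one primary study's group-level data.

    ``generating_correlation`` is the latent correlation between
    within-group relatedness and the outcome; ``design`` is
    ``"continuous"`` (relatedness varies across groups) or
    ``"two_arm"`` (low/high relatedness arms).  Outcomes are binomial
    mortality counts or negative-binomial pathogen counts aggregated to
    group means/SDs.
    """

    n_groups: int = 20
    group_size: int = 100
    outcome: str = "mortality"  # or "pathogen_count"
    generating_correlation: float = 0.0
    design: str = "continuous"
    baseline: float = 0.5   # mortality probability / log pathogen mean
    effect_scale: float = 0.2
    dispersion: float = 10.0

    def __post_init__(self) -> None:
        if self.n_groups < 4:
            raise ValueError("need at least 4 groups")
        if not -1 <= self.generating_correlation <= 1:
            raise ValueError("generating_correlation must lie in [-1, 1]")
        if self.outcome not in {"mortality", "pathogen_count"}:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.outcome == "mortality" and not 0 < self.baseline < 1:
            raise ValueError("mortality baseline must be a probability")
        if self.design not in {"continuous", "two_arm"}:
            raise ValueError(f"unknown design {self.design!r}")


def simulate_raw_groups(sim: RawStudySim, seed=None) -> pd.DataFrame:
    """Simulate one study's group-level summary table.

    Returns one row per group: ``relatedness`` (value or arm label),
    ``relatedness_sd``, ``outcome_mean``, ``outcome_sd``, ``n``
    (individuals per group) — the shape consumed by
    :func:`monoculture.effect_sizes.r_from_group_means` (after
    :func:`summarize_arms`) and ``resample_r_from_summaries``.
    """
    rng = np.random.default_rng(seed)
    k, rho = sim.n_groups, sim.generating_correlation
    if sim.design == "two_arm":
        x = np.repeat([-1.0, 1.0], [k // 2, k - k // 2])
        relatedness = np.where(x < 0, "low", "high")
        rel_sd = np.zeros(k)
    else:
        x = rng.standard_normal(k)
        relatedness = 0.25 + 0.15 * x
        rel_sd = np.full(k, 0.02)
    latent = rho * x + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal(k)
    if sim.outcome == "mortality":
        p = np.clip(sim.baseline + sim.effect_scale * latent, 0.01, 0.99)
        deaths = rng.binomial(sim.group_size, p)
        mean = deaths / sim.group_size
        sd = np.sqrt(mean * (1 - mean))
    else:
        mu = np.exp(np.log(max(sim.baseline, 1e-6)) + sim.effect_scale * latent)
        r_disp = sim.dispersion
        counts = rng.negative_binomial(
            r_disp, r_disp / (r_disp + mu[:, None]),
            size=(k, sim.group_size),
        )
        mean = counts.mean(axis=1)
        sd = counts.std(axis=1, ddof=1)
    return pd.DataFrame({
        "relatedness": relatedness,
        "relatedness_sd": rel_sd,
        "outcome_mean": mean,
        "outcome_sd": sd,
        "n": sim.group_size,
    })


def summarize_arms(groups: pd.DataFrame):
    """Collapse a two-arm group table to per-arm across-group summaries.

    Returns ``(low, high)`` :class:`~monoculture.effect_sizes.GroupSummary`
    objects where mean/SD are taken across the groups of each arm.
    """
    from .effect_sizes import GroupSummary

    out = []
    for arm in ("low", "high"):
        sub = groups[groups["relatedness"] == arm]["outcome_mean"]
        if len(sub) < 2:
            raise ValueError(f"arm {arm!r} has fewer than 2 groups")
        out.append(GroupSummary(
            mean=float(sub.mean()),
            sd=float(sub.std(ddof=1)),
            n_groups=len(sub),
            relatedness_level=arm,
        ))
    return tuple(out)


@dataclass(frozen=True)
class SelectionRule:
    """A publication-selection rule applied to an effect-size table.

    ``drop_prob`` removes qualifying records with that probability;
    ``inflate`` adds a constant to qualifying values.  ``condition``
    selects the stratum: ``"neg_high_v"`` (negative effect with
    above-median sampling variance — the classic funnel-asymmetry
    censoring) or ``"high_v"`` (above-median variance regardless of
    sign).  The identity rule (both zero) leaves the table unchanged.
    """

    drop_prob: float = 0.0
    inflate: float = 0.0
    condition: str = "neg_high_v"

    def __post_init__(self) -> None:
        if not 0 <= self.drop_prob < 1:
            raise ValueError("drop_prob must lie in [0, 1)")
        if not math.isfinite(self.inflate):
            raise ValueError("inflate must be finite")
        if self.condition not in {"neg_high_v", "high_v"}:
            raise ValueError(f"unknown condition {self.condition!r}")


def apply_selection_bias(
    table: pd.DataFrame, rule: SelectionRule, seed=None
) -> tuple[pd.DataFrame, dict]:
    """Censor/inflate a table per a selection rule; returns (table, info).

    ``info`` records the boolean qualifying mask and the dropped row
    labels so truth-aware tests can condition on the induced censoring.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    v = table["sampling_variance"].to_numpy(dtype=float)
    high_v = v > np.median(v)
    if rule.condition == "neg_high_v":
        qualifies = high_v & (table["value"].to_numpy(dtype=float) < 0)
    else:
        qualifies = high_v
    drop = qualifies & (rng.random(len(table)) < rule.drop_prob)
    out = table.loc[~drop].copy()
    if rule.inflate:
        keep_qualifies = pd.Series(qualifies, index=table.index).loc[out.index]
        out.loc[keep_qualifies, "value"] += rule.inflate
    if out.empty:
        raise ValueError("selection rule removed every record")
    info = {
        "qualifies": qualifies,
        "dropped_index": table.index[drop],
        "n_dropped": int(drop.sum()),
    }
    return out, info
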