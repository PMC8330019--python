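"""Synthetic longitudinal cohorts with planted treatment-response archetypes.

The generator emulates the study conditions end to end: four response
archetypes in the published proportions (58/87/138/64 of 347 complete
cases), per-archetype category distributions for the 12 consecutive
(metric, interval) response features, baseline covariate profiles and
rs37973 genotype frequencies, visit-level measurement trajectories that
invert the MCID classification rules exactly, and a missingness process
that reduces 365 enrolled patients to 347 complete cases.

Two planting modes are supported:

* ``"archetype"`` (default): every member of an archetype receives the
  archetype's *prototype* profile — the per-feature modal category of its
  distribution.  At ``noise_rate`` 0 archetype members are identical in
  response space, so the planted partition is exactly recoverable; this is
  the ground-truth regime used for cluster-recovery experiments.
* ``"marginal"``: each patient's category is drawn independently per
  feature from the archetype's distribution, so empirical per-archetype
  category frequencies reproduce the published tables.  The resulting
  within-archetype heterogeneity makes the planted labels only partially
  recoverable; see docs/methods.md.

``noise_rate`` resamples each planted category uniformly over the three
categories (the draw may repeat the original value).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from . import archetypes
from .response_rules import (
    CLUSTERING_FEATURES,
    CONSECUTIVE_INTERVALS,
    METRICS,
    ResponseCategory,
    ResponseRuleSet,
    VISIT_COLUMNS,
)

__all__ = [
    "SimulationConfig",
    "GenerationError",
    "sample_cohort",
    "realize_trajectories",
    "inject_missingness",
    "simulate_cohort",
    "write_cohort",
]

LUNG_BOUNDS = (0.2, 1.6)  # percent-predicted fraction support


class GenerationError(RuntimeError):
    """Raised when a planted category cannot be realized as measurements."""


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator.

    Defaults are the study conditions; see ``phenoresp.archetypes`` for the
    embedded table values.
    """

    n_enrolled: int = archetypes.N_ENROLLED
    archetype_proportions: tuple = archetypes.ARCHETYPE_SIZES
    #: feature -> (4, 3) probability rows; defaults to row-normalized counts
    category_distributions: dict = field(
        default_factory=archetypes.category_distributions)
    profile_sampling: str = "archetype"  # or "marginal"
    noise_rate: float = 0.0
    #: probability a patient loses one non-baseline visit
    missing_rate: float = 18 / 365
    #: when True, exactly round(n_enrolled * missing_rate) patients are hit
    deterministic_missingness: bool = True
    genotype_frequencies: dict = field(
        default_factory=archetypes.genotype_frequencies)
    baseline_control_probs: tuple = archetypes.BASELINE_CONTROL_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_sampling not in ("archetype", "marginal"):
            raise ValueError("profile_sampling must be 'archetype' or 'marginal'")
        if not 0 <= self.noise_rate <= 1:
            raise ValueError("noise_rate must lie in [0, 1]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if len(self.archetype_proportions) != 4:
            raise ValueError("exactly four archetype proportions required")
        for feature, probs in self.category_distributions.items():
            arr = np.asarray(probs, dtype=float)
            if arr.shape != (4, 3) or (arr < 0).any():
                raise ValueError(f"bad probability rows for {feature}")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"probability rows for {feature} must sum to 1")

    @property
    def archetype_counts(self) -> np.ndarray:
        """Deterministic allocation of archetype sizes (largest remainder)."""
        props = np.asarray(self.archetype_proportions, dtype=float)
        if props.sum() == self.n_enrolled and np.allclose(props, props.round()):
            return props.astype(int)
        quota = props / props.sum() * self.n_enrolled
        counts = np.floor(quota).astype(int)
        rem = self.n_enrolled - counts.sum()
        order = np.argsort(-(quota - counts))
        counts[order[:rem]] += 1
        return counts

    def to_yaml(self) -> str:
        payload = asdict(self)
        payload["category_distributions"] = {
            k: np.asarray(v).round(6).tolist()
            for k, v in self.category_distributions.items()}
        payload["genotype_frequencies"] = {
            k: np.asarray(v).round(6).tolist()
            for k, v in self.genotype_frequencies.items()}
        payload["archetype_proportions"] = list(self.archetype_proportions)
        payload["baseline_control_probs"] = list(self.baseline_control_probs)
        return yaml.safe_dump(payload, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# cohort sampling


def _ctrl_sequence_feasible(seq: tuple) -> bool:
    """Can some 0..2 control-level path realize these three categories?

    GOOD needs a strict decrease, POOR a strict increase, MODERATE no
    change; track the set of reachable levels across the three steps.
    """
    levels = {0, 1, 2}
    for cat in seq:
        if cat == 1:      # GOOD: any strictly lower level
            top = max(levels)
            levels = set(range(0, top)) if top > 0 else set()
        elif cat == 3:    # POOR: any strictly higher level
            bottom = min(levels)
            levels = set(range(bottom + 1, 3)) if bottom < 2 else set()
        if not levels:
            return False
    return True


def _prototype_ctrl_sequence(probs_by_interval: np.ndarray) -> tuple:
    """Max-probability feasible CTRL category sequence for one archetype.

    ``probs_by_interval`` is (3 intervals x 3 categories).  The per-interval
    modal sequence can be ordinally infeasible (three consecutive
    improvements on a 3-level scale), so the prototype maximizes the product
    of per-interval probabilities over feasible sequences; ties take the
    lexicographically smallest code sequence.
    """
    from itertools import product as iproduct
    best = None
    for seq in iproduct((1, 2, 3), repeat=3):
        if not _ctrl_sequence_feasible(seq):
            continue
        score = float(np.prod([probs_by_interval[i, c - 1]
                               for i, c in enumerate(seq)]))
        if best is None or score > best[0] + 1e-12 or (
                abs(score - best[0]) <= 1e-12 and seq < best[1]):
            best = (score, seq)
    return best[1]


def _planted_matrix(config: SimulationConfig, labels: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Planted category codes (n x 12) before noise."""
    dists = config.category_distributions
    n = len(labels)
    planted = np.empty((n, len(CLUSTERING_FEATURES)), dtype=int)
    ctrl_cols = {}
    for j, feature in enumerate(CLUSTERING_FEATURES):
        probs = np.asarray(dists[feature], dtype=float)
        if config.profile_sampling == "archetype":
            if feature.startswith("CTRL"):
                ctrl_cols[feature] = j
                continue  # filled jointly below (ordinal feasibility)
            planted[:, j] = probs.argmax(axis=1)[labels] + 1
        else:
            for a in range(4):
                mask = labels == a
                planted[mask, j] = rng.choice(
                    (1, 2, 3), size=int(mask.sum()), p=probs[a])
    if ctrl_cols:
        order = [f"CTRL_{iv}" for iv in CONSECUTIVE_INTERVALS]
        for a in range(4):
            probs_by_interval = np.stack(
                [np.asarray(dists[f], dtype=float)[a] for f in order])
            seq = _prototype_ctrl_sequence(probs_by_interval)
            mask = labels == a
            for i, feature in enumerate(order):
                planted[mask, ctrl_cols[feature]] = seq[i]
    return planted


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_cohort(config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw baselines, planted response profiles and truth labels.

    Returns ``(baselines, planted_profiles, truth_labels)``.  Archetype
    labels are allocated exactly in the configured proportions and then
    shuffled; baseline covariates come from per-archetype truncated-normal
    (continuous) or categorical (frequency) profiles.  The hidden archetype
    label appears only in the truth table.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    counts = config.archetype_counts
    labels = np.repeat(np.arange(4), counts)
    rng.shuffle(labels)
    n = len(labels)
    ids = [f"P{i:04d}" for i in range(1, n + 1)]

    planted = _planted_matrix(config, labels, rng)
    if config.noise_rate > 0:
        base = planted.copy()
        flip = rng.random(planted.shape) < config.noise_rate
        planted[flip] = rng.integers(1, 4, size=int(flip.sum()))
        # a noised CTRL triple can be ordinally infeasible (e.g. three
        # consecutive improvements on the 3-level scale); redraw the
        # perturbation of those cells until the sequence is realizable
        ctrl_cols = [j for j, f in enumerate(CLUSTERING_FEATURES)
                     if f.startswith("CTRL")]
        for i in range(planted.shape[0]):
            while not _ctrl_sequence_feasible(tuple(planted[i, ctrl_cols])):
                for j in ctrl_cols:
                    planted[i, j] = (rng.integers(1, 4)
                                     if rng.random() < config.noise_rate
                                     else base[i, j])

    base = {"patient_id": ids}
    for name, prof in archetypes.CONTINUOUS_PROFILES.items():
        lo, hi = prof["bounds"]
        col = np.empty(n)
        for a in range(4):
            mask = labels == a
            mean, sd = prof["per_archetype"][a]
            col[mask] = _truncnorm_draw(rng, mean, sd, lo, hi, int(mask.sum()))
        base[name] = col.round(2)
    for name, prof in archetypes.CATEGORICAL_PROFILES.items():
        col = np.empty(n, dtype=object)
        for a in range(4):
            mask = labels == a
            freqs = np.asarray(prof["per_archetype"][a], dtype=float)
            col[mask] = rng.choice(prof["labels"], size=int(mask.sum()),
                                   p=freqs / freqs.sum())
        base[name] = col
    for name, spec in archetypes.COHORT_CATEGORICALS.items():
        # keep categorical columns object-typed so downstream stages treat
        # 0/1 flags as categories, not continuous measurements
        base[name] = rng.choice(spec["labels"], size=n,
                                p=spec["probs"]).astype(object)
    for snp in archetypes.SNPS:
        probs = np.asarray(config.genotype_frequencies[snp], dtype=float)
        geno_labels = archetypes.GENOTYPE_LABELS[snp]
        col = np.empty(n, dtype=object)
        for a in range(4):
            mask = labels == a
            col[mask] = rng.choice(geno_labels, size=int(mask.sum()), p=probs[a])
        base[f"geno_{snp}"] = col
    # disease duration cannot exceed age
    base["disease_duration_years"] = np.minimum(
        base["disease_duration_years"], base["age_years"] - 0.5).round(2)

    baselines = pd.DataFrame(base)
    planted_df = pd.DataFrame(planted, columns=list(CLUSTERING_FEATURES))
    planted_df.insert(0, "patient_id", ids)
    truth = pd.DataFrame({"patient_id": ids, "archetype": labels + 1})
    return baselines, planted_df, truth


# ---------------------------------------------------------------------------
# trajectory realization (inverse of the classification rules)


def _sample_lung_end(rng, start, good_cut, category):
    """End value consistent with the planted lung-function category.

    A small margin keeps sampled values clear of the category boundaries so
    that rounding for CSV output cannot flip the classification.
    """
    lo, hi = LUNG_BOUNDS
    eps = 1e-3
    if category == ResponseCategory.GOOD:
        a, b = start + good_cut + eps, hi
    elif category == ResponseCategory.POOR:
        a, b = lo, start - good_cut - eps
    else:
        a = max(lo, start - good_cut + eps)
        b = min(hi, start + good_cut - eps)
    if a > b:
        return None
    return rng.uniform(a, b)


def _sample_feno_end(rng, start, high_cut, category, rules: ResponseRuleSet):
    """End value consistent with the planted FENO category."""
    eps = 0.05
    if start > high_cut:
        band = rules.feno_rel_change * start
        if category == ResponseCategory.POOR:
            a, b = start + band + eps, start + band + 30.0
        elif category == ResponseCategory.GOOD:
            a, b = 0.0, start - band - eps
        else:
            a, b = start - band + eps, start + band - eps
    else:
        band = rules.feno_abs_change
        if category == ResponseCategory.POOR:
            a, b = start + band + eps, start + band + 30.0
        elif category == ResponseCategory.GOOD:
            a, b = 0.0, start - band - eps
        else:
            a, b = max(0.0, start - band + eps), start + band - eps
    if a > b or b < 0:
        return None
    return rng.uniform(max(a, 0.0), b)


def _sample_ctrl_end(rng, start, category):
    if category == ResponseCategory.GOOD:
        choices = list(range(0, start))
    elif category == ResponseCategory.POOR:
        choices = list(range(start + 1, 3))
    else:
        choices = [start]
    if not choices:
        return None
    return int(rng.choice(choices))


# narrow planted sequences (e.g. chained large FENO decreases) can have
# per-attempt success rates of a few percent; the budget keeps the overall
# failure probability negligible while staying cheap
_MAX_PATIENT_ATTEMPTS = 2000


def _verify_roundtrip(plan, fev1, mef50, feno, ctrl, age, rules) -> bool:
    """Classification of the (rounded) realized values must match the plan."""
    from .response_rules import classify_control, classify_feno, classify_lungfunction
    for i, iv in enumerate(CONSECUTIVE_INTERVALS):
        if classify_lungfunction(fev1[i + 1] - fev1[i], rules.fev1_good_delta,
                                 rules.fev1_poor_delta) != plan[f"FEV1_{iv}"]:
            return False
        if classify_lungfunction(mef50[i + 1] - mef50[i], rules.mef50_good_delta,
                                 rules.mef50_poor_delta) != plan[f"MEF50_{iv}"]:
            return False
        if classify_feno(feno[i], feno[i + 1], age, rules) != plan[f"FENO_{iv}"]:
            return False
        if classify_control(ctrl[i], ctrl[i + 1]) != plan[f"CTRL_{iv}"]:
            return False
    return True


def _realize_patient(rng, planted_row: dict, baseline_row, rules: ResponseRuleSet,
                     control_probs=archetypes.BASELINE_CONTROL_PROBS,
                     visit0_sampler=None):
    """Visit-level values (4 visits) whose classification reproduces the plan.

    Values are rounded to the CSV output precision (lung function 4 dp,
    FENO 2 dp) and the round trip is verified before returning, so the
    written table classifies back to the planted categories exactly.

    Some planted sequences constrain the feasible visit-0 measurements
    (e.g. two consecutive GOOD FENO responses require a baseline above
    ~20 ppb under the absolute-change rule), so after a failed first
    attempt the visit-0 values are redrawn via ``visit0_sampler`` — the
    baseline measurement distribution conditioned on feasibility by
    rejection.
    """
    age = float(baseline_row.age_years)
    high_cut = rules.feno_high_cut(age)
    for attempt in range(_MAX_PATIENT_ATTEMPTS):
        if attempt == 0 or visit0_sampler is None:
            v0_fev1 = float(baseline_row.fev1_pp_baseline)
            v0_mef50 = float(baseline_row.mef50_pp_baseline)
            v0_feno = float(baseline_row.feno_baseline_ppb)
        else:
            v0_fev1, v0_mef50, v0_feno = visit0_sampler(rng)
        fev1 = [round(float(np.clip(v0_fev1, *LUNG_BOUNDS)), 4)]
        mef50 = [round(float(np.clip(v0_mef50, *LUNG_BOUNDS)), 4)]
        feno = [round(float(max(v0_feno, 0.0)), 2)]
        ctrl = [int(rng.choice((0, 1, 2), p=control_probs))]
        ok = True
        for iv in CONSECUTIVE_INTERVALS:
            cat_fev1 = planted_row[f"FEV1_{iv}"]
            cat_feno = planted_row[f"FENO_{iv}"]
            cat_ctrl = planted_row[f"CTRL_{iv}"]
            cat_mef = planted_row[f"MEF50_{iv}"]
            nxt_fev1 = _sample_lung_end(rng, fev1[-1], rules.fev1_good_delta, cat_fev1)
            nxt_mef = _sample_lung_end(rng, mef50[-1], rules.mef50_good_delta, cat_mef)
            nxt_feno = _sample_feno_end(rng, feno[-1], high_cut, cat_feno, rules)
            if iv.start == 0 and _sample_ctrl_end(rng, ctrl[0], cat_ctrl) is None:
                # planted change impossible from this baseline control level:
                # resample the baseline level from the feasible set
                feasible = [s for s in (0, 1, 2)
                            if _sample_ctrl_end(rng, s, cat_ctrl) is not None]
                ctrl[0] = int(rng.choice(feasible))
            nxt_ctrl = _sample_ctrl_end(rng, ctrl[-1], cat_ctrl)
            if None in (nxt_fev1, nxt_mef, nxt_feno, nxt_ctrl):
                ok = False
                break
            fev1.append(round(nxt_fev1, 4))
            mef50.append(round(nxt_mef, 4))
            feno.append(round(nxt_feno, 2))
            ctrl.append(nxt_ctrl)
        if ok and _verify_roundtrip(planted_row, fev1, mef50, feno, ctrl, age, rules):
            return fev1, mef50, feno, ctrl
    raise GenerationError(
        f"could not realize planted categories for patient "
        f"{baseline_row.patient_id} within {_MAX_PATIENT_ATTEMPTS} attempts")


def _default_visit0_sampler(row):
    """Redraw visit-0 measurements near a patient's drawn baseline values."""
    def draw(rng):
        fev1 = _truncnorm_draw(rng, row.fev1_pp_baseline, 0.15, *LUNG_BOUNDS, 1)[0]
        mef50 = _truncnorm_draw(rng, row.mef50_pp_baseline, 0.2, *LUNG_BOUNDS, 1)[0]
        feno = _truncnorm_draw(rng, row.feno_baseline_ppb, 12.0, 1.0, 150.0, 1)[0]
        return fev1, mef50, feno
    return draw


def realize_trajectories(baselines: pd.DataFrame, planted: pd.DataFrame,
                         rules: ResponseRuleSet = ResponseRuleSet(),
                         rng: Optional[np.random.Generator] = None,
                         visit0_samplers: Optional[dict] = None
                         ) -> pd.DataFrame:
    """Long-format visit table whose classification round-trips the plan.

    Visit-0 measurements come from the baseline profile (redrawn, if the
    planted sequence makes them infeasible, via the per-patient samplers —
    defaults re-centre on the patient's drawn baseline values); each later
    visit's values are sampled uniformly from the measurement region
    consistent with the planted category given the interval's start value.
    At noise 0 the classification of the returned table reproduces the
    planted categories exactly.  The realized visit-0 measurements are
    written back into ``baselines`` (columns ``fev1_pp_baseline``,
    ``mef50_pp_baseline``, ``feno_baseline_ppb``) so the two tables agree.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    planted = planted.set_index("patient_id")
    rows = []
    for i, b in enumerate(baselines.itertuples(index=False)):
        plan = planted.loc[b.patient_id].to_dict()
        plan = {k: ResponseCategory(int(v)) for k, v in plan.items()}
        sampler = (visit0_samplers or {}).get(b.patient_id,
                                              _default_visit0_sampler(b))
        fev1, mef50, feno, ctrl = _realize_patient(rng, plan, b, rules,
                                                   visit0_sampler=sampler)
        baselines.iloc[i, baselines.columns.get_loc("fev1_pp_baseline")] = fev1[0]
        baselines.iloc[i, baselines.columns.get_loc("mef50_pp_baseline")] = mef50[0]
        baselines.iloc[i, baselines.columns.get_loc("feno_baseline_ppb")] = feno[0]
        ics_tier = int(rng.choice((2, 3))) if b.ics_medhigh_v2_v3 else int(rng.choice((0, 1)))
        for v in range(4):
            rows.append({
                "patient_id": b.patient_id,
                "visit_index": v,
                "fev1_pp": round(fev1[v], 4),
                "mef50_pp": round(mef50[v], 4),
                "feno_ppb": round(feno[v], 2),
                "control_level": ctrl[v],
                "ics_dose_tier": ics_tier,
                "laba": int(b.laba),
                "ltra": int(b.ltra),
                "saba_used": int(b.saba_v2_v3) if v >= 2 else 0,
            })
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def inject_missingness(visits: pd.DataFrame, config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[pd.DataFrame, int]:
    """Blank all measurements of one random non-baseline visit per hit patient.

    Returns the modified table and the expected complete-case count.  In
    deterministic mode exactly ``round(n_enrolled * missing_rate)`` patients
    are affected; otherwise each patient is hit independently with
    probability ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    visits = visits.copy()
    ids = visits["patient_id"].unique()
    if config.deterministic_missingness:
        m = int(round(len(ids) * config.missing_rate))
        hit = rng.choice(ids, size=m, replace=False)
    else:
        hit = ids[rng.random(len(ids)) < config.missing_rate]
    measurement_cols = ["fev1_pp", "mef50_pp", "feno_ppb", "control_level"]
    for pid in hit:
        visit = int(rng.integers(1, 4))
        mask = (visits["patient_id"] == pid) & (visits["visit_index"] == visit)
        visits.loc[mask, measurement_cols] = np.nan
    return visits, len(ids) - len(hit)


def simulate_cohort(config: SimulationConfig, rules: ResponseRuleSet = ResponseRuleSet()
                    ) -> dict:
    """Full generator run: baselines, planted profiles, visits, truth labels.

    Returns a dict with keys ``baselines``, ``planted``, ``truth``,
    ``visits`` (after missingness) and ``expected_complete``.
    """
    rng = np.random.default_rng(config.seed)
    baselines, planted, truth = sample_cohort(config, rng)
    # feasibility redraws of visit-0 values use the archetype's own
    # measurement distributions
    profs = archetypes.CONTINUOUS_PROFILES
    label_of = dict(zip(truth["patient_id"], truth["archetype"] - 1))

    def archetype_sampler(a):
        def draw(rng):
            out = []
            for name in ("fev1_pp_baseline", "mef50_pp_baseline", "feno_baseline_ppb"):
                mean, sd = profs[name]["per_archetype"][a]
                lo, hi = profs[name]["bounds"]
                out.append(float(_truncnorm_draw(rng, mean, sd, lo, hi, 1)[0]))
            return tuple(out)
        return draw

    samplers = {pid: archetype_sampler(a) for pid, a in label_of.items()}
    visits = realize_trajectories(baselines, planted, rules, rng,
                                  visit0_samplers=samplers)
    visits, expected_complete = inject_missingness(visits, config, rng)
    return {"baselines": baselines, "planted": planted, "truth": truth,
            "visits": visits, "expected_complete": expected_complete}


def write_cohort(result: dict, config: SimulationConfig, out_dir) -> dict:
    """Write the generator outputs as CSV/YAML under ``out_dir``.

    Analysis-facing files (visits, baselines) never contain the archetype
    label; the truth table is a separate sidecar.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "visits": out / "visits.csv",
        "baselines": out / "baselines.csv",
        "truth": out / "truth_labels.csv",
        "planted": out / "planted_profiles.csv",
        "config": out / "config.yaml",
    }
    float_fmt = "%.4f"
    result["visits"].to_csv(paths["visits"], index=False, float_format=float_fmt)
    result["baselines"].to_csv(paths["baselines"], index=False, float_format=float_fmt)
    result["truth"].to_csv(paths["truth"], index=False)
    result["planted"].to_csv(paths["planted"], index=False)
    paths["config"].write_text(config.to_yaml())
    return paths
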