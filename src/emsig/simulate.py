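"""Synthetic survey generator with planted ground truth.

The generator emulates the structure the pipeline is meant to detect in a
vaccination-attitude cohort:

* per-scale item clusters — each item loads on one cluster latent; the
  loading and the between-cluster latent correlation are calibrated so the
  realized post-discretization Pearson correlations approach the configured
  within/between targets;
* reverse-phrased items, stored pre-reflected so that reverse scoring
  recovers alignment;
* an ordinal dose outcome (0..5) driven by the latent factors (or by the
  planted factor scores, or held constant) plus noise;
* demographic variables drawn from cohort category distributions, with
  per-subgroup overrides;
* planted subgroups that co-locate in factor space and in which a single
  "driving" factor splits doses.

Likert discretization thresholds a standard-normal item variable at
equiprobable cutpoints. Discretization attenuates correlations, so the
within/between targets refer to the post-discretization PCC: loadings are
backed out through an exact lookup of the discretized-correlation curve
(bivariate-normal rectangle probabilities), computed once per Likert length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .schema import MAX_DOSE, ScaleDefinition, SurveyDataset, SurveySchema

__all__ = [
    "ScaleSpec",
    "DoseModel",
    "SubgroupSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "ground_truth",
    "discretized_correlation",
    "latent_correlation_for",
    "study_like_config",
    "roi_recovery_config",
    "regression_config",
]


# ---------------------------------------------------------------------------
# correlation calibration under equiprobable Likert discretization

@lru_cache(maxsize=None)
def _disc_corr_curve(levels: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """(latent rho grid, discretized corr grid), both increasing."""
    cuts = stats.norm.ppf(np.arange(1, levels) / levels)
    vals = np.arange(1, levels + 1, dtype=float)
    mu = vals.mean()
    var = ((vals - mu) ** 2).mean()
    rhos = np.concatenate([[0.0], np.linspace(0.02, 0.995, 50)])
    out = []
    for rho in rhos:
        if rho == 0.0:
            out.append(0.0)
            continue
        cov = np.array([[1.0, rho], [rho, 1.0]])
        mvn = stats.multivariate_normal(mean=[0.0, 0.0], cov=cov)
        # CDF at every cutpoint pair, padded with the +/- inf limits
        big = np.empty((levels + 1, levels + 1))
        big[0, :] = 0.0
        big[:, 0] = 0.0
        big[-1, -1] = 1.0
        marg = stats.norm.cdf(cuts)
        big[1:-1, -1] = marg
        big[-1, 1:-1] = marg
        pts = np.array([[a, b] for a in cuts for b in cuts])
        big[1:-1, 1:-1] = mvn.cdf(pts).reshape(levels - 1, levels - 1)
        cell = (
            big[1:, 1:] - big[:-1, 1:] - big[1:, :-1] + big[:-1, :-1]
        )
        exy = float((vals[:, None] * vals[None, :] * cell).sum())
        out.append((exy - mu * mu) / var)
    return tuple(float(r) for r in rhos), tuple(float(v) for v in out)


def discretized_correlation(rho: float, levels: int) -> float:
    """Pearson correlation after equiprobable discretization of a bivariate
    standard normal with latent correlation ``rho`` into ``levels`` bins."""
    grid_r, grid_d = _disc_corr_curve(levels)
    return float(np.interp(rho, grid_r, grid_d))


def latent_correlation_for(target: float, levels: int) -> float:
    """Latent normal correlation whose discretized correlation is ``target``."""
    grid_r, grid_d = _disc_corr_curve(levels)
    if target > grid_d[-1]:
        raise ValueError(
            f"target PCC {target} not reachable after {levels}-level "
            f"discretization (max {grid_d[-1]:.3f})"
        )
    return float(np.interp(target, grid_d, grid_r))


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ScaleSpec:
    """Planted structure of one scale."""

    scale_id: str
    n_items: int
    n_clusters: int
    within_pcc: float = 0.7
    between_pcc: float = 0.1
    likert_min: int = 1
    likert_max: int = 5
    reverse_fraction: float = 0.2
    prefix: str = ""

    def __post_init__(self) -> None:
        if self.within_pcc <= self.between_pcc:
            raise ValueError(
                f"scale {self.scale_id!r}: within_pcc must exceed between_pcc"
            )
        if self.n_clusters > self.n_items:
            raise ValueError("more clusters than items")
        if not self.prefix:
            object.__setattr__(self, "prefix", self.scale_id[0].upper())

    @property
    def levels(self) -> int:
        return self.likert_max - self.likert_min + 1

    def item_ids(self) -> list[str]:
        return [f"{self.scale_id}_q{j + 1:02d}" for j in range(self.n_items)]

    def factor_ids(self) -> list[str]:
        return [f"{self.prefix}-c{c + 1}" for c in range(self.n_clusters)]

    def cluster_sizes(self) -> list[int]:
        base, extra = divmod(self.n_items, self.n_clusters)
        return [base + (1 if c < extra else 0) for c in range(self.n_clusters)]


@dataclass(frozen=True)
class DoseModel:
    """How the ordinal dose outcome is produced.

    ``basis="latent"`` combines the cluster latents, ``"factor_score"``
    combines the planted (aligned) per-cluster mean item scores, and
    ``"constant"`` fixes every background dose at round(intercept). The
    combination is standardized, scaled by ``slope``, shifted by
    ``intercept``, perturbed by N(0, noise_sd), rounded and clipped to 0..5.
    """

    basis: str = "latent"
    coefficients: tuple[tuple[str, float], ...] = ()
    intercept: float = 2.5
    slope: float = 1.2
    noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.basis not in ("latent", "factor_score", "constant"):
            raise ValueError(f"unknown dose basis {self.basis!r}")


@dataclass(frozen=True)
class SubgroupSpec:
    """A planted subpopulation co-located in factor space.

    Members' latents are replaced by ``center`` plus tight noise; the
    ``driving_factor`` latent instead spreads around ``driving_center``
    with ``driving_sd`` so that it can split doses. With a dose rule,
    members above the subgroup median of the driving variable receive
    ``dose_high`` and the rest ``dose_low``. The driving variable is the
    cluster LATENT by default (``dose_rule_basis="latent"``): item-level
    measurement noise then decouples the dose assignment from the
    respondent's position in any embedding of the observed scores, as in
    real data where attitudes are measured with error. With
    ``"factor_score"`` the observed mean item score drives the split
    instead. ``demographics`` overrides category distributions for the
    members.
    """

    fraction: float
    driving_factor: str
    center: float = 4.0
    tight_sd: float = 0.25
    driving_center: float = 0.0
    driving_sd: float = 0.5
    dose_low: int | None = 0
    dose_high: int | None = MAX_DOSE
    dose_rule_basis: str = "latent"
    #: factors given extra in-subgroup spread (sd ``spread_sd`` around the
    #: center); they carry the subgroup's internal geometry so that the
    #: driving factor does not dominate any embedding axis
    spread_factors: tuple[str, ...] = ()
    spread_sd: float = 0.35
    demographics: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("subgroup fraction must be in (0, 1)")
        if self.dose_rule_basis not in ("latent", "factor_score"):
            raise ValueError(f"unknown dose_rule_basis {self.dose_rule_basis!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    n_respondents: int
    scales: tuple[ScaleSpec, ...]
    dose_model: DoseModel = DoseModel()
    demographics: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    subgroups: tuple[SubgroupSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "scales", tuple(self.scales))
        object.__setattr__(self, "subgroups", tuple(self.subgroups))
        if sum(s.fraction for s in self.subgroups) >= 1.0:
            raise ValueError("subgroup fractions must sum to < 1")
        for var, dist in self.demographics:
            total = sum(p for _, p in dist)
            # published frequency tables carry rounding; renormalized at draw
            if abs(total - 1.0) > 0.02:
                raise ValueError(
                    f"demographic {var!r} distribution sums to {total}, not 1"
                )

    def factor_ids(self) -> list[str]:
        return [f for s in self.scales for f in s.factor_ids()]

    def schema(self) -> SurveySchema:
        """The survey schema matching generated output files."""
        return SurveySchema(
            scales=tuple(
                self._scale_definition(i, s) for i, s in enumerate(self.scales)
            ),
            dose_column="dose",
            demographic_columns=tuple(v for v, _ in self.demographics),
            id_column="respondent_id",
        )

    def _scale_definition(self, index: int, spec: ScaleSpec) -> ScaleDefinition:
        reverse = _reverse_items(
            spec, np.random.default_rng(_child_seed(self.seed, 0, index))
        )
        return ScaleDefinition(
            scale_id=spec.scale_id,
            item_ids=tuple(spec.item_ids()),
            likert_min=spec.likert_min,
            likert_max=spec.likert_max,
            reverse_items=frozenset(reverse),
            prefix=spec.prefix,
        )


@dataclass
class GroundTruth:
    """The planted structure behind one generated dataset."""

    item_partition: dict[str, dict[str, int]]
    factor_ids: list[str]
    latents: pd.DataFrame
    aligned_scores: pd.DataFrame
    subgroup_labels: pd.Series
    driving_factors: dict[int, str]

    def overall_item_labels(self) -> tuple[list[str], np.ndarray]:
        """Global (across scales) cluster labels for every item."""
        items, labels = [], []
        offset = 0
        for scale_id, part in self.item_partition.items():
            for item, c in part.items():
                items.append(item)
                labels.append(offset + c)
            offset += max(part.values()) + 1
        return items, np.array(labels, dtype=int)

    def subgroup_members(self, index: int = 0) -> np.ndarray:
        return np.flatnonzero(self.subgroup_labels.to_numpy() == index)


def _child_seed(seed: int, *stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(stream))


def _reverse_items(spec: ScaleSpec, rng: np.random.Generator) -> list[str]:
    n_rev = int(round(spec.reverse_fraction * spec.n_items))
    ids = spec.item_ids()
    picked = rng.choice(spec.n_items, size=n_rev, replace=False)
    return [ids[j] for j in sorted(picked)]


def _subgroup_assignment(config: SyntheticConfig) -> np.ndarray:
    """-1 for background, otherwise the subgroup index, seed-reproducible."""
    rng = np.random.default_rng(_child_seed(config.seed, 3))
    n = config.n_respondents
    labels = np.full(n, -1, dtype=int)
    perm = rng.permutation(n)
    start = 0
    for g, sub in enumerate(config.subgroups):
        size = int(round(sub.fraction * n))
        labels[perm[start : start + size]] = g
        start += size
    return labels


def ground_truth(config: SyntheticConfig) -> GroundTruth:
    """Planted structure (partition, memberships, driving factors) without
    generating item responses; latent/score frames are left empty."""
    partition = {}
    for spec in config.scales:
        ids = spec.item_ids()
        labels = np.repeat(np.arange(spec.n_clusters), spec.cluster_sizes())
        partition[spec.scale_id] = dict(zip(ids, labels.tolist()))
    labels = _subgroup_assignment(config)
    return GroundTruth(
        item_partition=partition,
        factor_ids=config.factor_ids(),
        latents=pd.DataFrame(),
        aligned_scores=pd.DataFrame(),
        subgroup_labels=pd.Series(labels, name="subgroup"),
        driving_factors={
            g: s.driving_factor
            for g, s in enumerate(config.subgroups)
            if s.dose_low is not None
        },
    )


def _discretize(cont: np.ndarray, spec: ScaleSpec) -> np.ndarray:
    cuts = stats.norm.ppf(np.arange(1, spec.levels) / spec.levels)
    return spec.likert_min + np.searchsorted(cuts, cont, side="right")


def generate_dataset(config: SyntheticConfig) -> tuple[SurveyDataset, GroundTruth]:
    """Generate a survey dataset and its ground truth; fully seed-determined."""
    n = config.n_respondents
    truth = ground_truth(config)
    sub_labels = truth.subgroup_labels.to_numpy()
    item_rng = np.random.default_rng(_child_seed(config.seed, 1))
    dose_rng = np.random.default_rng(_child_seed(config.seed, 2))
    demo_rng = np.random.default_rng(_child_seed(config.seed, 4))

    factor_ids = config.factor_ids()
    latents = np.empty((n, len(factor_ids)))
    aligned: dict[str, np.ndarray] = {}
    responses: dict[str, np.ndarray] = {}
    scale_defs = []
    col = 0
    for scale_index, spec in enumerate(config.scales):
        r_within = latent_correlation_for(spec.within_pcc, spec.levels)
        r_between = latent_correlation_for(spec.between_pcc, spec.levels)
        loading = np.sqrt(r_within)
        share = min(r_between / r_within, 0.95)  # latent corr between clusters
        g = item_rng.standard_normal(n)
        z_scale = []
        for c in range(spec.n_clusters):
            z = np.sqrt(share) * g + np.sqrt(1.0 - share) * item_rng.standard_normal(n)
            z_scale.append(z)
        # planted subgroups override the latents after the base draw
        for gidx, sub in enumerate(config.subgroups):
            members = sub_labels == gidx
            if not members.any():
                continue
            for c, fid in enumerate(spec.factor_ids()):
                if fid == sub.driving_factor:
                    z_scale[c][members] = (
                        sub.driving_center
                        + sub.driving_sd * item_rng.standard_normal(members.sum())
                    )
                else:
                    sd = (
                        sub.spread_sd
                        if fid in sub.spread_factors
                        else sub.tight_sd
                    )
                    z_scale[c][members] = (
                        sub.center + sd * item_rng.standard_normal(members.sum())
                    )
        ids = spec.item_ids()
        sizes = spec.cluster_sizes()
        reverse = set(
            _reverse_items(
                spec, np.random.default_rng(_child_seed(config.seed, 0, scale_index))
            )
        )
        j = 0
        for c, size in enumerate(sizes):
            fid = spec.factor_ids()[c]
            latents[:, col] = z_scale[c]
            cluster_values = []
            for _ in range(size):
                cont = loading * z_scale[c] + np.sqrt(
                    1.0 - loading**2
                ) * item_rng.standard_normal(n)
                values = _discretize(cont, spec)
                cluster_values.append(values.astype(float))
                item = ids[j]
                stored = (
                    spec.likert_min + spec.likert_max - values
                    if item in reverse
                    else values
                )
                responses[item] = stored.astype(int)
                j += 1
            aligned[fid] = np.mean(cluster_values, axis=0)
            col += 1
        scale_defs.append(
            ScaleDefinition(
                scale_id=spec.scale_id,
                item_ids=tuple(ids),
                likert_min=spec.likert_min,
                likert_max=spec.likert_max,
                reverse_items=frozenset(reverse),
                prefix=spec.prefix,
            )
        )

    latents_df = pd.DataFrame(latents, columns=factor_ids)
    aligned_df = pd.DataFrame(aligned, columns=factor_ids)

    # dose outcome
    dm = config.dose_model
    if dm.basis == "constant":
        cont = np.full(n, float(dm.intercept))
    else:
        basis = latents_df if dm.basis == "latent" else aligned_df
        coef = dict(dm.coefficients)
        if not coef:
            coef = {f: 1.0 for f in factor_ids}
        u = np.zeros(n)
        for f, w in coef.items():
            u += w * basis[f].to_numpy()
        sd = u.std()
        if sd > 0:
            u = (u - u.mean()) / sd
        cont = dm.intercept + dm.slope * u
    cont = cont + dm.noise_sd * dose_rng.standard_normal(n)
    dose = np.clip(np.round(cont), 0, MAX_DOSE).astype(int)

    for gidx, sub in enumerate(config.subgroups):
        if sub.dose_low is None or sub.dose_high is None:
            continue
        members = np.flatnonzero(sub_labels == gidx)
        basis_df = latents_df if sub.dose_rule_basis == "latent" else aligned_df
        drive = basis_df[sub.driving_factor].to_numpy()[members]
        high = drive > np.median(drive)
        dose[members[high]] = sub.dose_high
        dose[members[~high]] = sub.dose_low

    # demographics
    demo = {}
    for var, dist in config.demographics:
        cats = [c for c, _ in dist]
        probs = np.array([p for _, p in dist], dtype=float)
        probs = probs / probs.sum()
        draws = demo_rng.choice(len(cats), size=n, p=probs)
        values = np.array(cats, dtype=object)[draws]
        for gidx, sub in enumerate(config.subgroups):
            override = dict(sub.demographics).get(var)
            if override is None:
                continue
            members = np.flatnonzero(sub_labels == gidx)
            ocats = [c for c, _ in override]
            oprobs = np.array([p for _, p in override], dtype=float)
            oprobs = oprobs / oprobs.sum()
            odraw = demo_rng.choice(len(ocats), size=len(members), p=oprobs)
            values[members] = np.array(ocats, dtype=object)[odraw]
        demo[var] = values

    index = pd.RangeIndex(n, name="respondent_id")
    dataset = SurveyDataset(
        responses=pd.DataFrame(responses, index=index),
        dose=pd.Series(dose, index=index, name="dose"),
        demographics=pd.DataFrame(demo, index=index, dtype=str),
        scales=tuple(scale_defs),
    )
    latents_df.index = index
    aligned_df.index = index
    truth.latents = latents_df
    truth.aligned_scores = aligned_df
    truth.subgroup_labels.index = index
    return dataset, truth


# ---------------------------------------------------------------------------
# canned study conditions

#: Cohort category distributions following a published Deep-South survey
#: cohort's frequency table (proportions of n = 1020).
TABLE1_DEMOGRAPHICS: tuple = (
    ("sex", (("Male", 0.299), ("Female", 0.701))),
    (
        "race",
        (
            ("White", 0.696),
            ("Black", 0.218),
            ("Asian", 0.011),
            ("Other", 0.039),
            ("Multi-racial", 0.042),
        ),
    ),
    (
        "age",
        (
            ("18-24", 0.113),
            ("25-34", 0.154),
            ("35-44", 0.191),
            ("45-54", 0.199),
            ("55-64", 0.159),
            ("65+", 0.184),
        ),
    ),
    (
        "political_affiliation",
        (
            ("Republican", 0.417),
            ("Democrat", 0.205),
            ("Independent", 0.242),
            ("Something Else", 0.047),
            ("No answer", 0.089),
        ),
    ),
    ("flu_shot", (("Yes", 0.39), ("No", 0.61))),
    (
        "health_status",
        (
            ("Excellent", 0.118),
            ("Very Good", 0.279),
            ("Good", 0.368),
            ("Fair", 0.191),
            ("Poor", 0.044),
        ),
    ),
    ("insurance", (("Insured", 0.927), ("Not Insured", 0.073))),
)

#: Four scales, 85 items, 16 planted clusters (4 + 5 + 3 + 4): three
#: 5-point scales and one 4-point scale.
STUDY_SCALES: tuple[ScaleSpec, ...] = (
    ScaleSpec("CoVaH", 18, 4, likert_max=5, prefix="C"),
    ScaleSpec("T-DiG", 33, 5, likert_max=5, prefix="D"),
    ScaleSpec("TRUST-Ph", 15, 3, likert_max=5, prefix="P"),
    ScaleSpec("TiPHA", 19, 4, likert_max=4, prefix="G"),
)


def study_like_config(seed: int = 0, n: int = 1020) -> SyntheticConfig:
    """Default study-emulating conditions: 1020 respondents, 85 items in 16
    clusters (within-PCC 0.7, between 0.1), dose driven by three hesitancy
    latents, Table-1-like demographics, and one planted high-variance
    subgroup enriched for one political category."""
    return SyntheticConfig(
        n_respondents=n,
        scales=STUDY_SCALES,
        dose_model=DoseModel(
            basis="latent",
            coefficients=(("C-c1", -0.9), ("C-c2", -0.6), ("C-c4", -0.5)),
            intercept=2.0,
            slope=1.2,
            noise_sd=0.5,
        ),
        demographics=TABLE1_DEMOGRAPHICS,
        subgroups=(
            SubgroupSpec(
                fraction=0.1,
                driving_factor="C-c1",
                center=3.5,
                demographics=(
                    (
                        "political_affiliation",
                        (
                            ("Republican", 0.75),
                            ("Democrat", 0.05),
                            ("Independent", 0.1),
                            ("Something Else", 0.05),
                            ("No answer", 0.05),
                        ),
                    ),
                ),
            ),
        ),
        seed=seed,
    )


#: Analysis parameters that go with :func:`roi_recovery_config`. The
#: occupancy floor sits above the densest background cell (~55 members at
#: n = 2000) so cells outside the planted region carry no small-sample
#: mutual-information bias, while the subgroup's central cells (~100-180
#: members) stay live.
ROI_RECOVERY_ANALYSIS = {
    "occupancy_floor": 65,
    "pcc_floor": 0.55,
    "embed_method": "pca",
}


def roi_recovery_config(seed: int = 0, n: int = 2000) -> SyntheticConfig:
    """Planted-ROI scenario: one dense subgroup (20%) far out in factor
    space whose driving factor perfectly splits doses 0 vs 5, while every
    background dose is constant (the cleanest case of dose independence
    from the factors outside the region).

    Two designated "spread" factors carry the subgroup's internal 2D
    geometry with more variance than the driving factor's observed score,
    so the embedding does not sort members by dose; the driving score then
    varies freely inside each grid cell and the cell-median split aligns
    with the planted dose rule. Analyze with
    :data:`ROI_RECOVERY_ANALYSIS` (in particular its occupancy floor)."""
    return SyntheticConfig(
        n_respondents=n,
        scales=STUDY_SCALES,
        dose_model=DoseModel(basis="constant", intercept=2.0, noise_sd=0.0),
        demographics=TABLE1_DEMOGRAPHICS,
        subgroups=(
            SubgroupSpec(
                fraction=0.2,
                driving_factor="C-c1",
                center=4.0,
                tight_sd=0.12,
                driving_center=0.0,
                driving_sd=0.35,
                dose_low=0,
                dose_high=MAX_DOSE,
                dose_rule_basis="factor_score",
                spread_factors=("D-c1", "D-c2"),
                spread_sd=0.5,
            ),
        ),
        seed=seed,
    )


def regression_config(seed: int = 0, n: int = 1020) -> SyntheticConfig:
    """Regression-sanity scenario: dose is a linear function of three
    planted factor scores plus small noise, no planted subgroups."""
    return SyntheticConfig(
        n_respondents=n,
        scales=STUDY_SCALES,
        dose_model=DoseModel(
            basis="factor_score",
            coefficients=(("C-c1", 1.0), ("C-c2", 0.7), ("C-c4", 0.6)),
            intercept=2.5,
            slope=1.2,
            noise_sd=0.1,
        ),
        demographics=TABLE1_DEMOGRAPHICS,
        subgroups=(),
        seed=seed,
    )
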