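"""Study-shaped synthetic data: multi-environment dust communities with transfer.

The generator emulates the structure of a post-denoising amplicon study of
settled airborne dust across five indoor environments (cow/pig farmers'
homes, suburban homes, cow/pig stables) plus negative controls:

* each environment has a base log-abundance profile; a sample's latent
  composition is the softmax of that profile plus per-sample Gaussian noise
  (a logistic-normal community), so richness is controlled by the profile's
  steepness and sample scatter by the noise scale;
* each matched farm contributes one home and one stable sample; the home's
  latent composition is a mixture ``(1 - tau) * home draw + tau * own
  stable's realized composition``, so the transfer fraction ``tau`` acts on
  compositions (airborne mixing), not on counts;
* observed counts are a multinomial draw at a per-sample depth from a
  gamma-Poisson (overdispersed) depth distribution;
* negative controls are dominated by a dedicated block of contaminant
  features (present in controls with high probability, rarely
  cross-contaminating true samples) plus a faint sparse leak of biological
  features.

Everything is deterministic given the scenario seed, with per-sample streams
derived from ``(seed, sample_id)``.  The returned truth record keeps every
latent composition, the farm matching, and the contaminant feature ids, so
downstream statistics can be checked against the latent ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables_io import (
    HOME_ENVIRONMENT,
    RANKS,
    STABLE_ENVIRONMENT,
    FeatureTable,
    Metadata,
    SampleRecord,
    TaxonomyTable,
    derive_seed,
)

__all__ = [
    "EnvironmentSpec",
    "LivestockLink",
    "ContaminantSpec",
    "SyntheticScenario",
    "StudyTruth",
    "generate_study",
    "preset_study_shape",
]


@dataclass
class EnvironmentSpec:
    """One true-sample environment.

    ``sharpness`` scales the base log-abundance profile: steeper profiles
    concentrate reads on fewer features and so lower observed richness at a
    fixed depth.  ``sigma`` is the per-sample log-scale dispersion around the
    base.  An explicit ``base_logits`` vector overrides the generated profile.
    """

    name: str
    n_samples: int
    sharpness: float = 1.8
    sigma: float = 0.6
    base_logits: np.ndarray | None = None


@dataclass
class LivestockLink:
    """Matched home-stable pairs for one livestock type.

    ``tau`` overrides the scenario-level transfer fraction for this type.
    """

    livestock: str
    n_matched_farms: int
    tau: float | None = None


@dataclass
class ContaminantSpec:
    """Reagent-contaminant block carried by negative controls.

    ``mean_rel_abundance`` is the typical relative abundance of one
    contaminant when it crosses into a true sample.
    """

    n_features: int = 20
    prevalence_in_controls: float = 0.9
    prevalence_in_samples: float = 0.05
    mean_rel_abundance: float = 0.002


@dataclass
class SyntheticScenario:
    """Full generator parameterization; same seed implies bit-identical output.

    ``divergence`` in [0, 1] weights each environment's private direction
    against a template shared by all environments: 0 makes environments
    exchangeable, 1 makes their base profiles independent.
    """

    n_features: int
    environments: list[EnvironmentSpec]
    links: list[LivestockLink] = field(default_factory=list)
    n_controls: int = 0
    transfer_tau: float = 0.0
    divergence: float = 0.5
    depth_mean: float = 25_000.0
    depth_cv: float = 0.1
    contaminants: ContaminantSpec = field(default_factory=ContaminantSpec)
    #: weight of the sparse biological leak in negative controls
    control_leak: float = 0.02
    #: number of leaked biological features per control
    control_leak_features: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.transfer_tau <= 1.0):
            raise ValueError(f"transfer_tau must be in [0, 1], got {self.transfer_tau}")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError(f"divergence must be in [0, 1], got {self.divergence}")
        if self.n_features <= self.contaminants.n_features:
            raise ValueError("n_features must exceed the contaminant block size")
        by_name = {e.name: e for e in self.environments}
        for link in self.links:
            home = HOME_ENVIRONMENT.get(link.livestock)
            stable = STABLE_ENVIRONMENT.get(link.livestock)
            if home is None:
                raise ValueError(f"unknown livestock {link.livestock!r}")
            for env in (home, stable):
                spec = by_name.get(env)
                if spec is None:
                    raise ValueError(f"link {link.livestock!r}: environment {env} missing")
                if spec.n_samples < link.n_matched_farms:
                    raise ValueError(
                        f"link {link.livestock!r}: {link.n_matched_farms} matched farms "
                        f"but only {spec.n_samples} {env} samples"
                    )
            tau = link.tau if link.tau is not None else self.transfer_tau
            if not (0.0 <= tau <= 1.0):
                raise ValueError(f"link {link.livestock!r}: tau must be in [0, 1]")


@dataclass
class StudyTruth:
    """Latent ground truth of a generated study."""

    #: samples x features latent compositions (after transfer mixing and
    #: contaminant injection) from which counts were drawn
    latent_compositions: pd.DataFrame
    #: livestock -> farm_id -> (home_sample_id, stable_sample_id)
    matching: dict[str, dict[str, tuple[str, str]]]
    contaminant_ids: list[str]
    scenario: SyntheticScenario


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _draw_depth(rng: np.random.Generator, mean: float, cv: float) -> int:
    if cv <= 0:
        return max(1, int(round(mean)))
    shape = 1.0 / cv**2
    lam = rng.gamma(shape, mean / shape)
    return max(1, int(rng.poisson(lam)))


def generate_study(
    scenario: SyntheticScenario,
) -> tuple[FeatureTable, Metadata, TaxonomyTable, StudyTruth]:
    """Generate (FeatureTable, Metadata, TaxonomyTable, StudyTruth) for a scenario."""
    n_c = scenario.contaminants.n_features
    n_bio = scenario.n_features - n_c
    width = len(str(scenario.n_features))
    feature_ids = [f"ASV_{i + 1:0{width}d}" for i in range(scenario.n_features)]
    contaminant_ids = feature_ids[n_bio:]

    # Environment base profiles: shared template vs private direction.
    rng_base = np.random.default_rng(derive_seed(scenario.seed, "bases"))
    template = rng_base.standard_normal(n_bio)
    w = scenario.divergence
    bases: dict[str, np.ndarray] = {}
    for env in scenario.environments:
        if env.base_logits is not None:
            b = np.asarray(env.base_logits, dtype=float)
            if b.shape != (n_bio,):
                raise ValueError(
                    f"environment {env.name!r}: base_logits must have length {n_bio}"
                )
            bases[env.name] = b
        else:
            private = rng_base.standard_normal(n_bio)
            direction = np.sqrt(1.0 - w) * template + np.sqrt(w) * private
            bases[env.name] = env.sharpness * direction

    # Sample bookkeeping: stables first so matched homes can mix in their
    # own stable's realized composition.
    env_by_name = {e.name: e for e in scenario.environments}
    tau_by_livestock = {
        link.livestock: (link.tau if link.tau is not None else scenario.transfer_tau)
        for link in scenario.links
    }
    farms_by_livestock = {
        link.livestock: [
            f"{link.livestock}_farm_{k + 1:03d}" for k in range(link.n_matched_farms)
        ]
        for link in scenario.links
    }
    home_farm: dict[str, str] = {}  # home sample id -> farm id
    stable_farm: dict[str, str] = {}
    matching: dict[str, dict[str, tuple[str, str]]] = {}
    for link in scenario.links:
        home_env = HOME_ENVIRONMENT[link.livestock]
        stable_env = STABLE_ENVIRONMENT[link.livestock]
        matching[link.livestock] = {}
        for k, farm in enumerate(farms_by_livestock[link.livestock]):
            home_id = f"{home_env}_{k + 1:03d}"
            stable_id = f"{stable_env}_{k + 1:03d}"
            home_farm[home_id] = farm
            stable_farm[stable_id] = farm
            matching[link.livestock][farm] = (home_id, stable_id)

    stable_envs = set(STABLE_ENVIRONMENT.values())
    ordered_envs = sorted(
        scenario.environments, key=lambda e: (e.name not in stable_envs, e.name)
    )

    records: list[SampleRecord] = []
    sample_ids: list[str] = []
    comps: list[np.ndarray] = []
    counts_cols: list[np.ndarray] = []
    stable_bio_comp: dict[str, np.ndarray] = {}  # farm -> realized stable composition
    spec_c = scenario.contaminants

    def _contaminant_mix(
        rng: np.random.Generator, comp_bio: np.ndarray, prevalence: float
    ) -> np.ndarray:
        present = rng.random(n_c) < prevalence
        rel = np.where(
            present,
            rng.lognormal(np.log(spec_c.mean_rel_abundance), 0.5, size=n_c),
            0.0,
        )
        total = rel.sum()
        if total > 0.5:  # keep contamination a minority of reads in true samples
            rel *= 0.5 / total
            total = 0.5
        return np.concatenate([(1.0 - total) * comp_bio, rel])

    for env in ordered_envs:
        base = bases[env.name]
        for k in range(env.n_samples):
            sid = f"{env.name}_{k + 1:03d}"
            rng = np.random.default_rng(derive_seed(scenario.seed, "sample", sid))
            comp_bio = _softmax(base + env.sigma * rng.standard_normal(n_bio))
            farm = home_farm.get(sid)
            if farm is not None:
                livestock = farm.split("_farm_")[0]
                tau = tau_by_livestock[livestock]
                if tau > 0:
                    comp_bio = (1.0 - tau) * comp_bio + tau * stable_bio_comp[farm]
            if sid in stable_farm:
                stable_bio_comp[stable_farm[sid]] = comp_bio
            comp = _contaminant_mix(rng, comp_bio, spec_c.prevalence_in_samples)
            depth = _draw_depth(rng, scenario.depth_mean, scenario.depth_cv)
            counts = rng.multinomial(depth, comp / comp.sum())
            season = "summer" if k % 2 == 0 else "winter"
            records.append(
                SampleRecord(
                    sample_id=sid,
                    environment=env.name,
                    season=season,
                    farm_id=farm if farm is not None else stable_farm.get(sid),
                )
            )
            sample_ids.append(sid)
            comps.append(comp)
            counts_cols.append(counts)

    # Negative controls: contaminant-dominated with a faint sparse leak of
    # biological features (each control leaks a few random features).
    for k in range(scenario.n_controls):
        sid = f"negative_control_{k + 1:03d}"
        rng = np.random.default_rng(derive_seed(scenario.seed, "sample", sid))
        present = rng.random(n_c) < spec_c.prevalence_in_controls
        contam = np.where(present, rng.lognormal(0.0, 0.5, size=n_c), 0.0)
        leak = np.zeros(n_bio)
        n_leak = min(scenario.control_leak_features, n_bio)
        leak_idx = rng.choice(n_bio, size=n_leak, replace=False)
        leak[leak_idx] = rng.exponential(1.0, size=n_leak)
        comp = np.zeros(scenario.n_features)
        if contam.sum() > 0:
            comp[n_bio:] = (1.0 - scenario.control_leak) * contam / contam.sum()
            comp[:n_bio] = scenario.control_leak * leak / leak.sum()
        else:
            comp[:n_bio] = leak / leak.sum()
        depth = _draw_depth(rng, scenario.depth_mean, scenario.depth_cv)
        counts = rng.multinomial(depth, comp / comp.sum())
        records.append(
            SampleRecord(
                sample_id=sid,
                environment="negative_control",
                season="unknown",
                is_control=True,
            )
        )
        sample_ids.append(sid)
        comps.append(comp)
        counts_cols.append(counts)

    table = FeatureTable(
        np.column_stack(counts_cols).astype(np.int64), feature_ids, sample_ids
    )
    meta = Metadata(records)
    taxonomy = _synthetic_taxonomy(feature_ids, scenario.seed)
    truth = StudyTruth(
        latent_compositions=pd.DataFrame(
            np.vstack(comps), index=sample_ids, columns=feature_ids
        ),
        matching=matching,
        contaminant_ids=list(contaminant_ids),
        scenario=scenario,
    )
    return table, meta, taxonomy, truth


def _synthetic_taxonomy(feature_ids: list[str], seed: int) -> TaxonomyTable:
    """Placeholder lineages with realistic seven-rank structure.

    Features are hashed into a random hierarchy (8 phyla, nested classes /
    orders / families / genera); ~30% lack a species name and ~10% lack
    genus and species, always prefix-complete.
    """
    rng = np.random.default_rng(derive_seed(seed, "taxonomy"))
    lineages = {}
    for fid in feature_ids:
        p = rng.integers(1, 9)
        c = rng.integers(1, 4)
        o = rng.integers(1, 4)
        f = rng.integers(1, 5)
        g = rng.integers(1, 6)
        phylum = f"Phylum{p:02d}"
        cls = f"{phylum}_c{c}"
        order = f"{cls}_o{o}"
        family = f"{order}_f{f}"
        genus = f"{family}_g{g}"
        u = rng.random()
        if u < 0.10:
            lineage = ("Bacteria", phylum, cls, order, family, "", "")
        elif u < 0.40:
            lineage = ("Bacteria", phylum, cls, order, family, genus, "")
        else:
            lineage = ("Bacteria", phylum, cls, order, family, genus, f"{genus}_sp1")
        lineages[fid] = lineage
    assert len(lineages[feature_ids[0]]) == len(RANKS)
    return TaxonomyTable(lineages)


def preset_study_shape(seed: int = 0) -> SyntheticScenario:
    """The study-shaped scenario used throughout the package's examples.

    Group sizes follow the retained-sample design of a five-environment
    settled-dust study (65 suburban homes, 40 cow stables, 38 cow farmers'
    homes, 81 pig stables, 82 pig farmers' homes, 43 negative controls),
    2,000 features, per-sample depths overdispersed around 25,000 reads so
    that downstream subsampling to the 20,000-read analysis depth retains
    most samples.  Cow environments get flatter base profiles (higher
    richness) than pig environments, stables steeper than homes, and cow
    farms a larger transfer fraction than pig farms.
    """
    return SyntheticScenario(
        n_features=2000,
        environments=[
            EnvironmentSpec("suburban_home", 65, sharpness=1.8, sigma=1.2),
            EnvironmentSpec("cow_stable", 40, sharpness=2.1, sigma=1.2),
            EnvironmentSpec("cow_home", 38, sharpness=1.5, sigma=1.2),
            EnvironmentSpec("pig_stable", 81, sharpness=2.5, sigma=1.2),
            EnvironmentSpec("pig_home", 82, sharpness=1.9, sigma=1.2),
        ],
        links=[
            LivestockLink("cow", 29, tau=0.25),
            LivestockLink("pig", 77, tau=0.10),
        ],
        n_controls=43,
        divergence=0.35,
        depth_mean=25_000.0,
        depth_cv=0.1,
        contaminants=ContaminantSpec(
            n_features=25,
            prevalence_in_controls=0.9,
            prevalence_in_samples=0.05,
            mean_rel_abundance=0.002,
        ),
        seed=seed,
    )
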