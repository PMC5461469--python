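"""Synthetic dossier generator.

Produces datasets with the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any registry download:

* substances grouped into structural modules, each module sharing a core
  fingerprint bit pattern (high within-module Tanimoto, near-zero between);
* module-clustered acute oral toxicity with a configurable prevalence
  (default 268/1059 toxicants at the 2,000 mg/kg b.w. threshold);
* per-guideline LD50 values that pile up on dose-grid values (2,000 and
  5,000 mg/kg) because limit tests report the tested bound, with censoring
  qualifiers on limit-dose results;
* matched 28-day/90-day NOAEL pairs with positive log-scale correlation, a
  90-day marginal shifted low, and a small injected fraction of grossly
  discordant pairs (90d >> 28d);
* acute LD50 coupled to the 28-day NOAEL so the 200 mg/kg screening rule
  has a configurable negative/positive predictive value;
* GHS oral hazard flags H300-H305 derived from latent LD50 bands with
  configurable data-lacking/inconclusive rates.

Randomness is split into one child stream per artifact, so adding a stage
never perturbs earlier outputs, and everything is reproducible from
``(seed, config)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .dossier import (
    ACUTE_GUIDELINES,
    DESCRIPTOR_NAMES,
    HAZARD_CODES,
    StudyRecord,
    SubstanceRecord,
)

__all__ = ["GeneratorConfig", "ConfigError", "generate_fingerprints",
           "generate_acute_studies", "generate_repeated_dose_studies",
           "assign_hazard_flags", "generate_dossier"]

LOG_TOX_THRESHOLD = np.log10(2000.0)


class ConfigError(ValueError):
    """Generator configuration is internally inconsistent or infeasible."""


_DEFAULT_DOSE_GRIDS: dict[str, tuple[float, ...]] = {
    "TG401": (5.0, 50.0, 300.0, 2000.0, 5000.0),
    "TG420": (5.0, 50.0, 300.0, 2000.0),
    "TG423": (5.0, 50.0, 300.0, 2000.0, 5000.0),
    "TG425": (5.0, 50.0, 300.0, 2000.0, 5000.0),
}

# acute guideline usage shares (TG401 dominates historical registrations)
_GUIDELINE_PROBS = {"TG401": 0.76, "TG420": 0.11, "TG423": 0.11, "TG425": 0.02}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic dossier generator.

    All endpoint values are mg/kg body weight; latent endpoint models work
    in log10 units.
    """

    seed: int = 0
    n_substances: int = 1059
    n_modules: int = 9
    module_sizes: tuple[int, ...] | None = None
    fingerprint_length: int = 256
    within_module_similarity: float = 0.9
    #: probability a substance's toxicity follows its module's latent state
    clustering_strength: float = 0.9
    target_prevalence: float = 268 / 1059
    #: correlation between 28d and 90d log-NOAELs
    noael_correlation: float = 0.7
    dose_grids: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_DOSE_GRIDS)
    )
    guideline_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_GUIDELINE_PROBS)
    )
    #: probability a study value is snapped onto its guideline's dose grid
    p_snap: float = 0.5
    max_studies_per_substance: int = 3
    study_noise_sd_log10: float = 0.12
    toxic_log_ld50: tuple[float, float] = (2.5, 0.35)      # (mean, sd), ~316 mg/kg
    nontoxic_log_ld50: tuple[float, float] = (3.55, 0.30)  # ~3,550 mg/kg

    # repeated-dose block
    noael28_log_mean: float = 2.3   # ~200 mg/kg/day
    noael28_log_sd: float = 0.6
    shift_90d_log10: float = -0.15  # 90d marginal sits lower than 28d
    discordant_fraction: float = 0.02
    discordant_factor: float = 10.0
    p_noael_above_200: float = 0.63
    p_high90_given_high28: float = 0.70
    bulgheroni_npv: float = 0.945
    bulgheroni_ppv: float = 0.337

    # hazard flags
    hazard_lacking_rate: float = 0.05
    hazard_inconclusive_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("within_module_similarity", "clustering_strength",
                     "target_prevalence", "noael_correlation", "p_snap",
                     "p_noael_above_200", "p_high90_given_high28",
                     "bulgheroni_npv", "bulgheroni_ppv",
                     "hazard_lacking_rate", "hazard_inconclusive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.target_prevalence < 1.0:
            raise ConfigError("target_prevalence must be in (0, 1)")
        if not 0.0 < self.within_module_similarity <= 1.0:
            raise ConfigError("within_module_similarity must be in (0, 1]")
        if self.fingerprint_length < 64:
            raise ConfigError("fingerprint_length must be >= 64")
        if self.module_sizes is None:
            self.module_sizes = _default_module_sizes(
                self.n_substances, self.n_modules
            )
        else:
            self.module_sizes = tuple(int(m) for m in self.module_sizes)
        if sum(self.module_sizes) != self.n_substances:
            raise ConfigError("module_sizes must sum to n_substances")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes length must equal n_modules")

    # --- derived, deterministic pieces -------------------------------------

    def substance_ids(self) -> list[str]:
        width = max(4, len(str(self.n_substances)))
        return [f"S{i:0{width}d}" for i in range(self.n_substances)]

    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_modules), self.module_sizes)

    def stream(self, name: str) -> np.random.Generator:
        """Named child RNG stream split off the master seed."""
        order = ("fingerprints", "toxicity", "descriptors", "acute",
                 "repeated", "hazards")
        if name not in order:
            raise KeyError(name)
        children = np.random.SeedSequence(self.seed).spawn(len(order))
        return np.random.default_rng(children[order.index(name)])


def _default_module_sizes(n: int, m: int) -> tuple[int, int]:
    """Decreasing module sizes by largest-remainder apportionment."""
    weights = np.arange(m, 0, -1, dtype=float)
    quota = n * weights / weights.sum()
    sizes = np.floor(quota).astype(int)
    remainder = n - sizes.sum()
    order = np.argsort(-(quota - sizes), kind="stable")
    sizes[order[:remainder]] += 1
    return tuple(int(s) for s in sizes)


# ---------------------------------------------------------------------------
# latent toxicity


def latent_toxicity(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Latent toxicant flags and latent log10-LD50 per substance.

    Exactly ``round(n * target_prevalence)`` substances are toxicants. With
    clustering strength ``c``, a fraction ``c`` of the toxicants fills
    designated toxic modules (chosen to cover roughly the target count);
    the rest is scattered uniformly, so at ``c = 0`` the labels are
    independent of module membership and at ``c = 1`` toxic modules are
    label-pure.
    """
    rng = cfg.stream("toxicity")
    n = cfg.n_substances
    modules = cfg.module_assignment()
    n_tox = int(round(n * cfg.target_prevalence))
    c = cfg.clustering_strength

    toxic = np.zeros(n, dtype=bool)
    n_clustered = int(round(c * n_tox))

    # designate toxic modules: in shuffled order, take whole modules that
    # still fit the clustered budget (so full clustering yields label-pure
    # toxic modules); any leftover budget partially fills the next module
    module_order = rng.permutation(cfg.n_modules)
    remaining = n_clustered
    partial_candidates: list[int] = []
    for m in module_order:
        members = np.flatnonzero(modules == m)
        if len(members) <= remaining:
            toxic[members] = True
            remaining -= len(members)
        else:
            partial_candidates.append(m)
    for m in partial_candidates:
        if remaining == 0:
            break
        members = np.flatnonzero(modules == m)
        take = rng.choice(members, size=min(remaining, len(members)),
                          replace=False)
        toxic[take] = True
        remaining -= len(take)

    remaining = n_tox - int(toxic.sum())
    if remaining > 0:
        candidates = np.flatnonzero(~toxic)
        scattered = rng.choice(candidates, size=remaining, replace=False)
        toxic[scattered] = True

    mu_t, sd_t = cfg.toxic_log_ld50
    mu_n, sd_n = cfg.nontoxic_log_ld50
    log_ld50 = np.empty(n, dtype=float)
    log_ld50[toxic] = _truncated_normal(
        rng, mu_t, sd_t, upper=LOG_TOX_THRESHOLD, size=int(toxic.sum())
    )
    log_ld50[~toxic] = _truncated_normal(
        rng, mu_n, sd_n, lower=LOG_TOX_THRESHOLD, size=int((~toxic).sum())
    )
    return toxic, log_ld50


def _truncated_normal(rng, mean, sd, size, lower=-np.inf, upper=np.inf):
    if sd == 0:
        return np.full(size, np.clip(mean, lower, upper))
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                               random_state=rng)


# ---------------------------------------------------------------------------
# fingerprints and descriptors


def generate_fingerprints(cfg: GeneratorConfig) -> list[SubstanceRecord]:
    """Substances with module-structured fingerprints and descriptors.

    Each module owns a disjoint block of ``K`` core bits. A member keeps
    each core bit with probability ``1 - mu`` and gains each non-core bit
    with a small rate chosen to keep the expected on-bit count near ``K``.
    Ignoring the additive noise, the expected Tanimoto similarity of two
    members is ``(1 - mu) / (1 + mu)``; ``mu`` is solved from the requested
    within-module similarity with a 0.8 safety factor so the realized
    expectation stays at or above the request. Between-module similarity is
    near zero because cores are disjoint.
    """
    L = cfg.fingerprint_length
    m = cfg.n_modules
    K = max(8, L // (2 * m))
    if K * m > L:
        raise ConfigError("fingerprint_length too small for this many modules")
    floor = K / (2 * L - K)  # expected similarity of two unrelated patterns
    if cfg.within_module_similarity <= floor:
        raise ConfigError(
            f"within_module_similarity {cfg.within_module_similarity} at or "
            f"below the achievable floor {floor:.3f}"
        )
    # With per-core-bit drop rate mu and an additive rate keeping the
    # expected popcount at K, the expected pairwise Tanimoto is
    # (1-mu)^2 / (1 - mu^2 + 2 mu); solving for mu at the requested
    # similarity gives 1 - sqrt(2s/(1+s)); the 0.85 factor keeps the
    # realized expectation at or above the request.
    s = cfg.within_module_similarity
    mu = 0.85 * (1.0 - np.sqrt(2.0 * s / (1.0 + s)))

    rng = cfg.stream("fingerprints")
    modules = cfg.module_assignment()
    ids = cfg.substance_ids()

    cores = np.zeros((m, L), dtype=np.uint8)
    for j in range(m):
        cores[j, j * K:(j + 1) * K] = 1

    add_rate = mu * K / (L - K) if mu > 0 else 0.0
    fingerprints = np.zeros((cfg.n_substances, L), dtype=np.uint8)
    for i in range(cfg.n_substances):
        core = cores[modules[i]]
        fp = core.copy()
        if mu > 0:
            drop = rng.random(L) < mu
            add = rng.random(L) < add_rate
            fp = np.where(core == 1, np.where(drop, 0, 1),
                          np.where(add, 1, 0)).astype(np.uint8)
        if fp.sum() == 0:  # keep at least one bit so Tanimoto is defined
            fp[modules[i] * K] = 1
        fingerprints[i] = fp

    toxic, log_ld50 = latent_toxicity(cfg)
    descriptors = _generate_descriptors(cfg, modules, toxic, log_ld50)

    records = []
    for i, sid in enumerate(ids):
        records.append(
            SubstanceRecord(
                substance_id=sid,
                fingerprint=fingerprints[i],
                descriptors={name: float(descriptors[i, j])
                             for j, name in enumerate(DESCRIPTOR_NAMES)},
                module=int(modules[i]),
            )
        )
    return records


def _generate_descriptors(cfg, modules, toxic, log_ld50) -> np.ndarray:
    """27-column descriptor matrix with module structure and toxicity signal.

    Bond-polarizability (Bpol) and polar-surface-area (TPSA) carry a strong
    global toxicity signal (non-toxicants score higher on Bpol, mirroring
    the 'small labile molecules are more acutely toxic' pattern); the
    remaining descriptors mix module-specific means, a weak random toxicity
    loading, and noise.
    """
    rng = cfg.stream("descriptors")
    n = len(modules)
    p = len(DESCRIPTOR_NAMES)
    module_means = rng.normal(0.0, 1.0, size=(cfg.n_modules, p))
    loadings = rng.normal(0.0, 0.25, size=p)
    X = module_means[modules] + np.outer(np.where(toxic, 1.0, -1.0), loadings)
    X += rng.normal(0.0, 1.0, size=(n, p))

    names = list(DESCRIPTOR_NAMES)
    z = (log_ld50 - log_ld50.mean()) / max(log_ld50.std(), 1e-9)
    # strong, named signal carriers
    X[:, names.index("Bpol")] = 12.0 + 1.1 * z + rng.normal(0, 1.0, n)
    X[:, names.index("TPSA")] = 60.0 + 9.0 * z + rng.normal(0, 9.0, n)
    X[:, names.index("Weight")] = 250.0 + 40.0 * module_means[modules, 0] \
        + rng.normal(0, 30.0, n)
    return X


# ---------------------------------------------------------------------------
# acute studies


def generate_acute_studies(
    substances: Sequence[SubstanceRecord], cfg: GeneratorConfig
) -> list[StudyRecord]:
    """1-3 acute oral studies per substance with dose-grid pile-ups.

    Study values are drawn around the substance's latent log-LD50 with
    truncation to the latent toxicity side of 2,000 mg/kg, then snapped
    (with probability ``p_snap``) to the nearest dose-grid value of the
    assigned guideline *on the same side of 2,000*, producing the
    characteristic pile-ups at 2,000/5,000 without flipping class labels.
    Every substance receives at least one Klimisch-1 key study; limit-dose
    results at the grid top carry a ``greater_equal`` censoring qualifier.
    """
    rng = cfg.stream("acute")
    toxic, log_ld50 = latent_toxicity(cfg)
    if len(substances) != cfg.n_substances:
        raise ConfigError("substances do not match the generator config")

    guidelines = list(cfg.guideline_probs)
    gl_p = np.array([cfg.guideline_probs[g] for g in guidelines], dtype=float)
    gl_p = gl_p / gl_p.sum()

    studies: list[StudyRecord] = []
    for i, sub in enumerate(substances):
        n_studies = rng.integers(1, cfg.max_studies_per_substance + 1)
        is_tox = bool(toxic[i])
        for j in range(n_studies):
            guideline = guidelines[rng.choice(len(guidelines), p=gl_p)]
            if is_tox:
                lv = _truncated_normal(rng, log_ld50[i],
                                       cfg.study_noise_sd_log10, 1,
                                       upper=LOG_TOX_THRESHOLD - 1e-9)[0]
            else:
                lv = _truncated_normal(rng, log_ld50[i],
                                       cfg.study_noise_sd_log10, 1,
                                       lower=LOG_TOX_THRESHOLD)[0]
            value = 10.0 ** lv
            qualifier = "exact"
            if rng.random() < cfg.p_snap:
                grid = np.asarray(cfg.dose_grids.get(guideline, ()), float)
                side = grid < 2000.0 if is_tox else grid >= 2000.0
                grid = grid[side]
                if grid.size:
                    value = float(grid[np.argmin(np.abs(np.log10(grid) - lv))])
                    if not is_tox:
                        # limit test: the bound itself is reported
                        qualifier = "greater_equal" if rng.random() < 0.7 else "exact"
            if j == 0:
                klimisch, key, ra = 1, True, False
            else:
                klimisch = int(rng.choice([1, 2, 3, 4], p=[0.4, 0.3, 0.2, 0.1]))
                key = False
                ra = bool(rng.random() < 0.1)
            studies.append(
                StudyRecord(
                    substance_id=sub.substance_id,
                    endpoint="acute_oral",
                    guideline=guideline,
                    klimisch=klimisch,
                    is_key_study=key,
                    is_read_across=ra,
                    value_mg_per_kg=value,
                    qualifier=qualifier,
                )
            )
    return studies


# ---------------------------------------------------------------------------
# repeated-dose studies (with coupled acute LD50)


def generate_repeated_dose_studies(
    substances: Sequence[SubstanceRecord], cfg: GeneratorConfig
) -> list[StudyRecord]:
    """Matched 28d/90d NOAEL pairs plus NOAEL-coupled acute studies.

    The 28-day log-NOAEL is drawn around ``noael28_log_mean`` conditioned
    on whether the substance sits above or below the 200 mg/kg screening
    threshold (probability ``p_noael_above_200``). The 90-day value follows
    a bivariate log-normal with correlation ``noael_correlation`` and a
    shifted-low marginal; when the 28-day NOAEL is >= 1,000 mg/kg the
    90-day high/low category is resampled to hit
    ``p_high90_given_high28`` (skipped when correlation is exactly 1, which
    degenerates to equal pairs). A ``discordant_fraction`` of pairs is
    overwritten with 90d = 28d * ``discordant_factor`` to emulate the
    flagged anomalies. The acute LD50 class is drawn conditionally on the
    28d screening category so the 200 mg/kg rule has NPV
    ``bulgheroni_npv`` and PPV ``bulgheroni_ppv`` in expectation.
    """
    rng = cfg.stream("repeated")
    mu28, sd28 = cfg.noael28_log_mean, cfg.noael28_log_sd
    rho = cfg.noael_correlation
    log200 = np.log10(200.0)
    log1000 = np.log10(1000.0)
    mu_t, sd_t = cfg.toxic_log_ld50
    mu_n, sd_n = cfg.nontoxic_log_ld50

    studies: list[StudyRecord] = []
    for sub in substances:
        above200 = rng.random() < cfg.p_noael_above_200
        if above200:
            l28 = _truncated_normal(rng, mu28, sd28, 1, lower=log200)[0]
        else:
            l28 = _truncated_normal(rng, mu28, sd28, 1, upper=log200)[0]

        resid_sd = sd28 * np.sqrt(max(0.0, 1.0 - rho * rho))
        if rho >= 1.0 and cfg.shift_90d_log10 == 0.0:
            l90 = l28
        else:
            l90 = (cfg.shift_90d_log10 + mu28 + rho * (l28 - mu28)
                   + rng.normal(0.0, resid_sd))
            if rho < 1.0 and l28 >= log1000:
                high90 = rng.random() < cfg.p_high90_given_high28
                if high90 and l90 < log1000:
                    l90 = _truncated_normal(
                        rng, cfg.shift_90d_log10 + mu28 + rho * (l28 - mu28),
                        max(resid_sd, 1e-6), 1, lower=log1000)[0]
                elif not high90 and l90 >= log1000:
                    l90 = _truncated_normal(
                        rng, cfg.shift_90d_log10 + mu28 + rho * (l28 - mu28),
                        max(resid_sd, 1e-6), 1, upper=log1000 - 1e-9)[0]
        if rng.random() < cfg.discordant_fraction:
            l90 = l28 + np.log10(cfg.discordant_factor)

        # acute class coupled to the 28d screening category
        if above200:
            is_tox = rng.random() < (1.0 - cfg.bulgheroni_npv)
        else:
            is_tox = rng.random() < cfg.bulgheroni_ppv
        if is_tox:
            ld = _truncated_normal(rng, mu_t, sd_t, 1,
                                   upper=LOG_TOX_THRESHOLD - 1e-9)[0]
        else:
            ld = _truncated_normal(rng, mu_n, sd_n, 1,
                                   lower=LOG_TOX_THRESHOLD)[0]

        sid = sub.substance_id
        studies.append(StudyRecord(sid, "repeated_28d", "TG407",
                                   int(rng.choice([1, 2], p=[0.7, 0.3])),
                                   True, False, 10.0 ** l28))
        studies.append(StudyRecord(sid, "repeated_90d", "TG408",
                                   int(rng.choice([1, 2], p=[0.7, 0.3])),
                                   True, False, 10.0 ** l90))
        studies.append(StudyRecord(sid, "acute_oral", "TG401", 1, True, False,
                                   10.0 ** ld))
    return studies


# ---------------------------------------------------------------------------
# hazard flags


_HAZARD_BANDS = {  # positive when latent LD50 falls in (lo, hi]
    "H300": (0.0, 50.0),
    "H301": (50.0, 300.0),
    "H302": (300.0, 2000.0),
    "H303": (2000.0, 5000.0),
}


def assign_hazard_flags(
    substances: Sequence[SubstanceRecord],
    ld50_values: np.ndarray,
    cfg: GeneratorConfig,
) -> None:
    """Fill H300-H305 statuses from latent LD50 bands, in place.

    H300-H303 follow the GHS acute-category dose bands; the aspiration
    hazards H304/H305 are independent rare positives with a high
    data-lacking rate. Each flag is masked to ``data_lacking`` or
    ``inconclusive`` at the configured rates.
    """
    rng = cfg.stream("hazards")
    for sub, ld50 in zip(substances, ld50_values):
        flags: dict[str, str] = {}
        for code, (lo, hi) in _HAZARD_BANDS.items():
            flags[code] = "positive" if lo < ld50 <= hi else "negative"
        for code in ("H304", "H305"):
            if rng.random() < 0.45:
                flags[code] = "data_lacking"
            else:
                flags[code] = "positive" if rng.random() < 0.05 else "negative"
        for code in HAZARD_CODES:
            u = rng.random()
            if u < cfg.hazard_lacking_rate:
                flags[code] = "data_lacking"
            elif u < cfg.hazard_lacking_rate + cfg.hazard_inconclusive_rate:
                flags[code] = "inconclusive"
        sub.hazard_flags = flags


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class Dossier:
    """Everything one pipeline run consumes."""

    substances: list[SubstanceRecord]
    acute_studies: list[StudyRecord]
    repeated_studies: list[StudyRecord]
    config: GeneratorConfig

    @property
    def latent_toxic(self) -> np.ndarray:
        return latent_toxicity(self.config)[0]


def generate_dossier(cfg: GeneratorConfig) -> Dossier:
    """Generate substances, acute studies, repeated-dose studies and flags."""
    substances = generate_fingerprints(cfg)
    acute = generate_acute_studies(substances, cfg)
    repeated = generate_repeated_dose_studies(substances, cfg)
    _, log_ld50 = latent_toxicity(cfg)
    assign_hazard_flags(substances, 10.0 ** log_ld50, cfg)
    return Dossier(substances, acute, repeated, cfg)
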