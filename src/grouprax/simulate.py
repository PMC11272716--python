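"""Synthetic multi-omics grouping/read-across studies with known ground truth.

The generator emulates the structure of an acute-exposure omics bridging
study: a panel of substances (default seven, in three planted
bioactivity groups of sizes 3/2/2), three dose levels descending in
half-log10 steps from each substance's equi-effective dose, three sampling
time points, substance-specific untreated controls, and three omics layers —
two mass-spectrometry intensity layers (log-normal noise) and one
transcript-count layer (negative-binomial noise, fewer replicates).

Substances in the same planted group share a sparse per-layer effect
template (a random loading over a "responsive" feature subset) whose
magnitude scales monotonically with dose and time; one designated
source/target pair additionally shares an extra template component so the
planted analogue is recoverable.  Optional extras: dose-proportional
xenobiotic spike-in features at known m/z, and structural fingerprints with
planted family-shared and family-unique bits.

What this emulates — and what it does not: planted effects are clean
multiplicative shifts with i.i.d. noise; real data carry batch drift,
QC-sample structure, correlated features and heavy annotation uncertainty,
none of which are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTROL_DOSE, Exclusion, StudyDesign, TreatmentGroup
from .matrix import FeatureMatrix
from .readacross import PotencyRecord, derive_dose_ladder, resolve_nonresponsive
from .structure import FINGERPRINT_LENGTH
from .xenobiotic import PROTON_MASS, MassTarget

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_study",
    "simulate_fingerprints",
    "spike_xenobiotics",
    "azo_study_config",
    "AZO_SUBSTANCES",
    "AZO_EXCLUSIONS",
]

#: The seven-substance azo-dye panel with its planted bioactivity groups.
AZO_SUBSTANCES = {
    "DY3": "G1", "S1": "G1", "SRG": "G1",
    "DO25": "G2", "DR1": "G2",
    "DR13": "G3", "DO61": "G3",
}

#: Missing-treatment-group preset: immobilisation losses (3) + QC removals (2).
AZO_EXCLUSIONS = [
    Exclusion("S1", "medium", "48h", "immobilisation"),
    Exclusion("S1", "high", "48h", "immobilisation"),
    Exclusion("DO61", "high", "48h", "immobilisation"),
    Exclusion("DO25", "low", "2h", "qc"),
    Exclusion("DO25", "medium", "2h", "qc"),
]

#: Synthetic stand-in potencies.  S1's chronic NOEC/LOEC (40/60 ug/L) and the
#: potency order S1 > DY3 are the study facts; other numbers are invented.
AZO_POTENCY = [
    PotencyRecord("S1", 1.0, True, noec=40.0, loec=60.0),
    PotencyRecord("SRG", 1.5, True),
    PotencyRecord("DY3", 2.0, True),
    PotencyRecord("DR1", 2.5, True),
    PotencyRecord("DR13", 3.0, True),
    PotencyRecord("DO61", 4.0, True, noec=300.0, loec=500.0),
    PotencyRecord("DO25", None, False),
]

#: Synthetic parent neutral monoisotopic masses (Da) for spike-ins.
AZO_PARENT_MASSES = {
    "DY3": 269.0800, "S1": 248.0950, "SRG": 278.1055, "DR1": 314.1379,
    "DR13": 348.0989, "DO25": 323.1382, "DO61": 368.0343,
}


@dataclass
class SimConfig:
    """Tunable description of one synthetic study; defaults mirror the
    seven-substance azo-dye panel."""

    substances: dict[str, str] = field(default_factory=lambda: dict(AZO_SUBSTANCES))
    analogue_pairs: dict[str, str] = field(default_factory=lambda: {"DY3": "S1"})
    dose_levels: tuple[str, ...] = ("low", "medium", "high")
    time_points: tuple[str, ...] = ("2h", "24h", "48h")
    #: features per layer (intensity, intensity, counts)
    n_features: dict[str, int] = field(
        default_factory=lambda: {"polar": 245, "apolar": 183, "transcriptomics": 1889}
    )
    replicates: dict[str, int] = field(
        default_factory=lambda: {"polar": 6, "apolar": 6, "transcriptomics": 4}
    )
    #: planted effect size: log-scale shift in units of the feature noise sd,
    #: reached at the highest dose/time multiplier
    effect_z: float = 3.0
    effect_fraction: float = 0.10  # fraction of features responsive per layer
    dose_multipliers: tuple[float, float, float] = (0.6, 0.8, 1.0)
    time_multipliers: tuple[float, float, float] = (0.5, 0.8, 1.0)
    pair_share: float = 1.2    # extra template weight shared by the analogue pair
    member_jitter: float = 0.15  # within-group template individuality
    sigma_lognormal: float = 0.3   # intensity noise sd (natural log scale)
    nb_dispersion: float = 0.05    # negative-binomial dispersion alpha
    count_baseline_log_mean: float = np.log(200.0)
    count_baseline_log_sd: float = 1.2
    intensity_baseline_log_mean: float = np.log(1e5)
    intensity_baseline_log_sd: float = 1.0
    exclusions: list[Exclusion] = field(default_factory=list)
    potency: list[PotencyRecord] = field(default_factory=lambda: list(AZO_POTENCY))
    parent_masses: dict[str, float] = field(default_factory=lambda: dict(AZO_PARENT_MASSES))
    spike_xeno: bool = True
    # fingerprint template
    n_bits: int = FINGERPRINT_LENGTH
    global_bits: int = 5
    shared_extra_per_family: int = 6
    unique_per_family: dict[str, int] = field(
        default_factory=lambda: {"G1": 2, "G2": 3, "G3": 3}
    )
    background_density: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.dose_multipliers, self.dose_multipliers[1:])):
            raise ValueError("dose multipliers must be strictly increasing")
        if min(self.replicates.values()) < 2:
            raise ValueError("need at least 2 replicates per group")
        groups = set(self.substances.values())
        if not groups:
            raise ValueError("no substances configured")
        if self.sigma_lognormal <= 0 or self.nb_dispersion <= 0:
            raise ValueError("noise parameters must be positive")

    @property
    def partition(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for s, g in self.substances.items():
            out.setdefault(g, []).append(s)
        return out

    def nominal_doses(self) -> dict[str, dict[str, float]]:
        """Half-log10 dose ladders anchored at each equi-effective dose."""
        resolved = {p.substance: p for p in resolve_nonresponsive(self.potency)}
        out = {}
        for s in self.substances:
            high = resolved[s].equi_effective_dose if s in resolved else 1.0
            low, med, hi = derive_dose_ladder(high)
            out[s] = dict(zip(self.dose_levels, (low, med, hi)))
        return out


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    partition: dict[str, list[str]]
    analogues: dict[str, str]
    responsive_features: dict[str, list[str]]
    spiked_features: dict[str, str] = field(default_factory=dict)
    spiked_mz: dict[str, float] = field(default_factory=dict)
    unique_bits: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class SimulatedStudy:
    """A complete synthetic study: matrices, design, inputs and ground truth."""

    layers: dict[str, FeatureMatrix]
    design: StudyDesign
    truth: GroundTruth
    config: SimConfig
    potency: list[PotencyRecord]
    fingerprints: pd.DataFrame | None = None
    mass_targets: list[MassTarget] = field(default_factory=list)

    @property
    def nominal_doses(self) -> dict[str, dict[str, float]]:
        return self.config.nominal_doses()


def _member_templates(cfg: SimConfig, n_resp: int, rng: np.random.Generator):
    """Per-substance effect loadings over the responsive feature subset.

    Group templates (and the analogue pair's extra component) are drawn
    i.i.d. normal and then orthogonalised against each other, so distinct
    planted mechanisms share nothing by construction; each member adds its
    own jitter on top.
    """
    n_tpl = len(cfg.partition) + len(cfg.analogue_pairs)
    raw = rng.standard_normal((max(n_tpl, 1), n_resp))
    if n_resp >= n_tpl > 1:
        q, _ = np.linalg.qr(raw.T)
        raw = q.T[:n_tpl] * np.sqrt(n_resp)
    group_tpl = {g: raw[i] for i, g in enumerate(cfg.partition)}
    pair_tpl = {
        pair: raw[len(cfg.partition) + i]
        for i, pair in enumerate(cfg.analogue_pairs.items())
    }
    tpl = {}
    j = cfg.member_jitter
    for s, g in cfg.substances.items():
        base = group_tpl[g].copy()
        for (target, source), extra in pair_tpl.items():
            if s in (target, source):
                base = base + cfg.pair_share * extra
        vec = np.sqrt(1 - j**2) * base / np.linalg.norm(base) * np.sqrt(n_resp) \
            + j * rng.standard_normal(n_resp)
        tpl[s] = vec
    return tpl


def _endogenous_mz(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Distinct endogenous feature m/z values, kept >20 ppm from any target."""
    targets = np.array(
        [m + PROTON_MASS for m in cfg.parent_masses.values()] or [0.0]
    )
    out: list[float] = []
    while len(out) < n:
        mz = rng.uniform(70.0, 1000.0, size=2 * (n - len(out)))
        ppm = np.abs(mz[:, None] - targets) / targets * 1e6
        out.extend(np.round(mz[(ppm > 20).all(axis=1)], 4))
        out = list(dict.fromkeys(out))
    return np.sort(np.array(out[:n]))


def simulate_study(cfg: SimConfig | None = None) -> SimulatedStudy:
    """Generate all omics layers plus design, potency table and ground truth.

    Treated replicates are baseline x exp(template x dose x time multiplier)
    with layer noise; controls are baseline noise only.  Excluded treatment
    groups are absent from the output.  Same seed, same study, bit for bit.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    design = StudyDesign(
        substances=list(cfg.substances),
        dose_levels=list(cfg.dose_levels),
        time_points=list(cfg.time_points),
        replicates_per_group=max(cfg.replicates.values()),
        exclusions=list(cfg.exclusions),
        nominal_doses=cfg.nominal_doses(),
    )
    retained = set(design.retained_groups())
    dose_mult = dict(zip(cfg.dose_levels, cfg.dose_multipliers))
    time_mult = dict(zip(cfg.time_points, cfg.time_multipliers))

    truth = GroundTruth(
        partition=cfg.partition,
        analogues=dict(cfg.analogue_pairs),
        responsive_features={},
    )
    layers: dict[str, FeatureMatrix] = {}
    for layer, n_feat in cfg.n_features.items():
        is_count = layer == "transcriptomics"
        n_rep = cfg.replicates[layer]
        if is_count:
            feat_ids = [f"gene_{i:04d}" for i in range(n_feat)]
        else:
            feat_ids = [f"mz_{m:.4f}" for m in _endogenous_mz(cfg, n_feat, rng)]
        n_resp = max(1, int(round(cfg.effect_fraction * n_feat))) if cfg.effect_z > 0 else 0
        resp_idx = rng.choice(n_feat, size=n_resp, replace=False) if n_resp else np.array([], int)
        truth.responsive_features[layer] = [feat_ids[i] for i in resp_idx]
        tpl = _member_templates(cfg, n_resp, rng) if n_resp else {s: None for s in cfg.substances}

        if is_count:
            baseline = np.exp(
                rng.normal(cfg.count_baseline_log_mean, cfg.count_baseline_log_sd, n_feat)
            )
            # per-gene log-scale noise of a negative binomial
            noise_sd = np.sqrt(cfg.nb_dispersion + 1.0 / baseline)
        else:
            baseline = np.exp(
                rng.normal(cfg.intensity_baseline_log_mean, cfg.intensity_baseline_log_sd, n_feat)
            )
            noise_sd = np.full(n_feat, cfg.sigma_lognormal)
        # standardised effect: log-scale shift of effect_z feature noise sds
        # at the full dose/time multiplier (an effect size, not a t-statistic)
        delta_amp = cfg.effect_z * noise_sd

        rows, meta_rows = [], []
        for s in cfg.substances:
            cells: list[tuple[str, str, float]] = [
                (CONTROL_DOSE, t, 0.0) for t in cfg.time_points
            ]
            for d in cfg.dose_levels:
                for t in cfg.time_points:
                    if TreatmentGroup(s, d, t) in retained:
                        cells.append((d, t, dose_mult[d] * time_mult[t]))
            for d, t, mult in cells:
                delta = np.zeros(n_feat)
                if n_resp and mult > 0:
                    delta[resp_idx] = delta_amp[resp_idx] * mult * tpl[s]
                for rep in range(n_rep):
                    if is_count:
                        mean = baseline * np.exp(delta)
                        lam = rng.gamma(1.0 / cfg.nb_dispersion, mean * cfg.nb_dispersion)
                        vals = rng.poisson(lam).astype(float)
                    else:
                        vals = np.exp(
                            np.log(baseline) + delta + rng.normal(0, noise_sd, n_feat)
                        )
                    sid = f"{layer[:2]}_{s}_{d}_{t}_r{rep + 1}"
                    rows.append(vals)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "substance": s,
                            "dose_level": d,
                            "time_point": t,
                            "replicate": rep + 1,
                            "batch": "b1",
                        }
                    )
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        values = pd.DataFrame(np.vstack(rows), index=meta.index, columns=feat_ids)
        layers[layer] = FeatureMatrix(layer, values, meta)

    targets: list[MassTarget] = []
    if cfg.spike_xeno and cfg.parent_masses and "apolar" in layers:
        targets = [
            MassTarget(substance=s, label="parent", neutral_mass=m)
            for s, m in cfg.parent_masses.items()
        ]
        layers["apolar"] = spike_xenobiotics(layers["apolar"], cfg, truth, rng)

    fps = simulate_fingerprints(cfg, truth, rng)
    return SimulatedStudy(
        layers=layers,
        design=design,
        truth=truth,
        config=cfg,
        potency=list(cfg.potency),
        fingerprints=fps,
        mass_targets=targets,
    )


def spike_xenobiotics(
    fm: FeatureMatrix,
    cfg: SimConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Append one dose-proportional parent-dye feature per substance.

    Spiked m/z sits within 2 ppm of the theoretical protonated mass;
    intensity is exactly proportional to the nominal dose in that
    substance's treated samples and zero elsewhere (controls included) —
    the idealised internal-exposure signal.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if not cfg.parent_masses:
        return fm
    doses = cfg.nominal_doses()
    values = fm.values.copy()
    for s, mass in cfg.parent_masses.items():
        if s not in cfg.substances:
            continue
        theo = mass + PROTON_MASS
        mz = theo * (1 + rng.uniform(-2, 2) * 1e-6)
        fid = f"xeno_{s}_{mz:.5f}"
        col = np.zeros(fm.n_samples)
        sel = (fm.meta["substance"] == s) & (fm.meta["dose_level"] != CONTROL_DOSE)
        dose_of = fm.meta.loc[sel, "dose_level"].map(doses[s])
        col[np.flatnonzero(sel.to_numpy())] = dose_of.to_numpy() * 1e4
        values[fid] = col
        if truth is not None:
            truth.spiked_features[s] = fid
            truth.spiked_mz[s] = mz
    return FeatureMatrix(fm.layer, values, fm.meta)


def simulate_fingerprints(
    cfg: SimConfig,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Binary fingerprints with planted family structure.

    Bits: a handful set in every substance (the common scaffold), per-family
    shared bits also set in one outsider (shared but not unique),
    per-family unique bits set in all members and nowhere else, and sparse
    i.i.d. background.  Any background bit that lands in every member of a
    family is cleared in one member so the planted unique counts are exact.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    subs = list(cfg.substances)
    partition = cfg.partition
    n_planted = (
        cfg.global_bits
        + len(partition) * cfg.shared_extra_per_family
        + sum(cfg.unique_per_family.get(g, 0) for g in partition)
    )
    if n_planted > cfg.n_bits:
        raise ValueError("planted bits exceed fingerprint length")
    bit_names = [f"bit_{i:03d}" for i in range(cfg.n_bits)]
    fps = pd.DataFrame(0, index=subs, columns=bit_names, dtype=int)
    pool = list(rng.permutation(cfg.n_bits))

    def take(k: int) -> list[int]:
        out = [pool.pop() for _ in range(k)]
        return out

    planted: set[int] = set()
    for b in take(cfg.global_bits):
        fps.iloc[:, b] = 1
        planted.add(b)
    unique_bits: dict[str, list[str]] = {}
    for g, members in partition.items():
        outsiders = [s for s in subs if s not in members]
        for b in take(cfg.shared_extra_per_family):
            fps.loc[members, bit_names[b]] = 1
            if outsiders:
                fps.loc[rng.choice(outsiders), bit_names[b]] = 1
            planted.add(b)
        ub = take(cfg.unique_per_family.get(g, 0))
        for b in ub:
            fps.loc[members, bit_names[b]] = 1
            planted.add(b)
        unique_bits[g] = [bit_names[b] for b in ub]
    # sparse background on unplanted positions only
    for b in range(cfg.n_bits):
        if b in planted:
            continue
        mask = rng.random(len(subs)) < cfg.background_density
        fps.iloc[:, b] = mask.astype(int)
    # keep planted unique counts exact: no background bit may cover a family
    for g, members in partition.items():
        block = fps.loc[members]
        for bit in fps.columns[block.all(axis=0)]:
            b = bit_names.index(bit)
            if b not in planted:
                fps.loc[members[int(rng.integers(len(members)))], bit] = 0
    if truth is not None:
        truth.unique_bits = unique_bits
    return fps


def azo_study_config(
    seed: int = 0, missing_groups: bool = False, **overrides
) -> SimConfig:
    """The seven-substance study preset.

    ``missing_groups=True`` applies the historical missing-treatment-group
    pattern (three immobilisation losses, two QC removals).  The default
    study is the complete factorial: with unbalanced time-point
    availability, the maximum-perturbation collapse systematically shrinks
    the profile norms of substances with fewer time points (the largest of
    two draws is stochastically smaller than of three), an artefact that
    can rival the planted signal at benchmark effect sizes.
    """
    if missing_groups and "exclusions" not in overrides:
        overrides["exclusions"] = list(AZO_EXCLUSIONS)
    return SimConfig(seed=seed, **overrides)
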