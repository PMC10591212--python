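"""Ground-truthed synthetic collagen sequences and simulated MALDI spectra.

The generator enforces collagen-likeness by construction — glycine at every
third position, proline-rich X/Y positions, K/R at a collagen-realistic
frequency — rather than learning from real sequences. Species are derived
from a common ancestral chain by planting recorded substitutions at X/Y
positions; substitutions never create or destroy a K/R (or a glycine), so
tryptic spans stay homologous across species and the discovered marker panel
can be cross-checked exactly against the recorded substitution sites.

Spectrum simulation draws every per-peptide random quantity unconditionally
and applies peak dropout as a threshold on a pre-drawn uniform deviate, so
cohorts simulated from the same seed at different dropout probabilities are
coupled (common random numbers): the degraded cohort is the clean one with a
monotonically growing set of peaks removed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np

from zoomskit.collagen_seq import CHAIN_IDS, CollagenChain, SpeciesProfile
from zoomskit.digest import DigestParams, tryptic_peptides
from zoomskit.masscalc import HYDROXYLATION, ModificationCaps, mh
from zoomskit.spectra import Spectrum

#: X/Y residue pool for substitutions: no G (triplet structure), no K/R
#: (cleavage sites), no X
_SUB_POOL = "ASTDENQLVFHMIP"


@dataclass(frozen=True)
class SyntheticSpeciesConfig:
    """Parameters of the synthetic multi-species collagen set.

    ``substitution_rate`` is the per-X/Y-position probability that a species
    differs from the ancestral chain; ``cleavage_density`` is the K/R
    frequency among X/Y draws (sets mean tryptic fragment length);
    ``proline_prob`` makes X/Y positions proline-rich, as in real collagen.
    """

    n_species: int = 4
    triplets_per_chain: int = 340
    substitution_rate: float = 0.008
    cleavage_density: float = 0.11
    proline_prob: float = 0.30
    propeptide_n: int = 30
    propeptide_c: int = 15
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need n_species >= 2")
        for r in (self.substitution_rate, self.cleavage_density, self.proline_prob):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class Substitution:
    """One planted inter-species difference at a mature-chain position."""

    species_id: str
    chain_id: str
    mature_pos: int  # 1-based
    ref: str
    alt: str


@dataclass(frozen=True)
class PeptideEmission:
    """One peptide peak (possibly dropped) of one simulated spectrum."""

    chain_id: str
    start: int
    sequence: str
    n_oh: int
    mz_true: float
    mz_observed: float
    intensity: float
    dropped: bool


@dataclass
class SampleTruth:
    sample_id: str
    species_id: str
    emissions: list[PeptideEmission] = field(default_factory=list)


@dataclass
class TruthManifest:
    """Everything needed to score the pipeline against the generator."""

    species_ids: tuple[str, ...]
    substitutions: tuple[Substitution, ...]
    samples: dict[str, SampleTruth] = field(default_factory=dict)

    def residues_at(self, chain_id: str, pos: int) -> dict[str, str]:
        """Per-species residue at a substituted position."""
        subs = [
            s
            for s in self.substitutions
            if s.chain_id == chain_id and s.mature_pos == pos
        ]
        if not subs:
            raise KeyError(f"no substitution recorded at {chain_id} {pos}")
        ref = subs[0].ref
        out = {sp: ref for sp in self.species_ids}
        for s in subs:
            out[s.species_id] = s.alt
        return out

    def variable_positions(self) -> set[tuple[str, int]]:
        """(chain, mature position) sites where >= 2 species differ."""
        keys = {(s.chain_id, s.mature_pos) for s in self.substitutions}
        return {
            k for k in keys if len(set(self.residues_at(*k).values())) >= 2
        }

    def unique_carrier(self, chain_id: str, pos: int) -> str | None:
        """The single species differing from all others, if there is one."""
        res = self.residues_at(chain_id, pos)
        for sp, r in res.items():
            others = {v for s, v in res.items() if s != sp}
            if len(others) == 1 and r not in others:
                return sp
        return None


def _draw_xy(rng: np.random.Generator, cfg: SyntheticSpeciesConfig) -> str:
    u = rng.random()
    if u < cfg.proline_prob:
        return "P"
    if u < cfg.proline_prob + cfg.cleavage_density:
        return "K" if rng.random() < 0.5 else "R"
    return _SUB_POOL[rng.integers(len(_SUB_POOL))]


def make_species(
    cfg: SyntheticSpeciesConfig = SyntheticSpeciesConfig(),
) -> tuple[list[SpeciesProfile], TruthManifest]:
    """Generate species profiles from one ancestor with recorded substitutions.

    Deterministic per ``cfg.seed``. Glycine at every third mature position is
    preserved in all species; substitutions occur only at X/Y positions and
    never touch K/R, so all species share identical tryptic spans.
    """
    rng = np.random.default_rng(cfg.seed)
    species_ids = tuple(f"sp{i + 1}" for i in range(cfg.n_species))
    ancestors: dict[str, tuple[str, str, str]] = {}
    for chain_id in CHAIN_IDS:
        mature = "".join(
            "G" + _draw_xy(rng, cfg) + _draw_xy(rng, cfg)
            for _ in range(cfg.triplets_per_chain)
        )
        pre = "".join(
            _SUB_POOL[rng.integers(len(_SUB_POOL))] for _ in range(cfg.propeptide_n)
        )
        post = "".join(
            _SUB_POOL[rng.integers(len(_SUB_POOL))] for _ in range(cfg.propeptide_c)
        )
        ancestors[chain_id] = (pre, mature, post)

    substitutions: list[Substitution] = []
    profiles: list[SpeciesProfile] = []
    for sp in species_ids:
        chains = []
        for chain_id in CHAIN_IDS:
            pre, mature, post = ancestors[chain_id]
            residues = list(mature)
            for i, ref in enumerate(residues):
                if ref in "GKR":
                    continue  # keep triplet structure and cleavage sites
                after_cut = i > 0 and residues[i - 1] in "KR"
                if after_cut and ref == "P":
                    # a P guarding a K/R-P bond: substituting it would move a
                    # cleavage site and break span homology
                    continue
                if rng.random() < cfg.substitution_rate:
                    alt = ref
                    while alt == ref or (after_cut and alt == "P"):
                        alt = _SUB_POOL[rng.integers(len(_SUB_POOL))]
                    residues[i] = alt
                    substitutions.append(
                        Substitution(sp, chain_id, i + 1, ref, alt)
                    )
            full = pre + "".join(residues) + post
            chains.append(
                CollagenChain(
                    species_id=sp,
                    chain_id=chain_id,
                    residues=full,
                    mature_start=len(pre) + 1,
                    mature_end=len(pre) + len(mature),
                )
            )
        profiles.append(SpeciesProfile(sp, tuple(chains)))
    return profiles, TruthManifest(species_ids, tuple(substitutions))


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Acquisition and degradation model for simulated MALDI spectra.

    Defaults describe a clean, externally calibrated reflector-mode spectrum
    of well-preserved collagen: small global calibration error (ppm), small
    per-peak jitter (Da), ~0.3 Da FWHM peaks, log-normal intensities over an
    exponentially decaying baseline, sparse spurious noise peaks, and a
    per-proline hydroxylation probability that produces the characteristic
    ~16 Da ladders. ``dropout`` removes whole peptide peaks, emulating poor
    preservation.
    """

    calibration_ppm: float = 5.0
    jitter_sd: float = 0.01
    fwhm: float = 0.3
    intensity_mu: float = 4.0
    intensity_sigma: float = 0.5
    baseline_amp: float = 20.0
    baseline_decay: float = 700.0
    noise_sd: float = 0.5
    noise_peak_rate: float = 0.01  # spurious (non-collagen) peaks per 100 Da
    noise_peak_mu_offset: float = -3.0  # log-intensity offset of spurious peaks
    hydroxylation_prob: float = 0.30
    dropout: float = 0.0
    mz_min: float = 800.0
    mz_max: float = 3600.0
    grid_step: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.dropout <= 1:
            raise ValueError("dropout must lie in [0, 1]")
        for v in (self.jitter_sd, self.fwhm, self.noise_sd, self.noise_peak_rate):
            if v < 0:
                raise ValueError("noise parameters must be nonnegative")

    @classmethod
    def clean(cls) -> "SpectrumNoiseModel":
        return cls()

    def with_dropout(self, p: float) -> "SpectrumNoiseModel":
        return replace(self, dropout=p)


@functools.lru_cache(maxsize=200_000)
def _mh_cached(seq: str, n_oh: int) -> float:
    return mh(seq, n_oh)


def _peptide_table(
    profile: SpeciesProfile,
    dparams: DigestParams,
    noise: SpectrumNoiseModel,
    max_oh: int,
) -> list[tuple[str, int, str, int, float]]:
    """(chain, start, sequence, oh capacity, base mass) rows worth simulating."""
    rows = []
    for chain in profile.chains:
        for pep in tryptic_peptides(chain, dparams):
            base = _mh_cached(pep.sequence, 0)
            cap = min(max_oh, HYDROXYLATION.capacity(pep.sequence))
            if base > noise.mz_max or base + cap * HYDROXYLATION.delta < noise.mz_min:
                continue
            rows.append((pep.chain_id, pep.start, pep.sequence, cap, base))
    return rows


def simulate_spectrum(
    profile: SpeciesProfile,
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    dparams: DigestParams = DigestParams(),
    caps: ModificationCaps = ModificationCaps(),
    seed: int = 0,
    sample_id: str | None = None,
    _table: list | None = None,
) -> tuple[Spectrum, SampleTruth]:
    """Simulate one profile-mode MALDI spectrum of one species.

    Deterministic per seed. Every emitted (or dropped) peptide peak is
    recorded in the returned :class:`SampleTruth`.
    """
    rng = np.random.default_rng(seed)
    sid = sample_id or f"{profile.species_id}_sim"
    table = (
        _table
        if _table is not None
        else _peptide_table(profile, dparams, noise, caps.max_hydroxylations)
    )
    truth = SampleTruth(sid, profile.species_id)
    emitted: list[tuple[float, float]] = []
    for chain_id, start, seq, cap, _base in table:
        # draw all randomness unconditionally: keeps cohorts with different
        # dropout levels coupled under a shared seed
        u_drop = rng.random()
        n_p = HYDROXYLATION.capacity(seq)
        n_oh = min(int(rng.binomial(n_p, noise.hydroxylation_prob)), cap)
        jitter = rng.normal(0.0, noise.jitter_sd) if noise.jitter_sd else 0.0
        intensity = float(
            np.exp(rng.normal(noise.intensity_mu, noise.intensity_sigma))
        )
        dropped = u_drop < noise.dropout
        mz_true = _mh_cached(seq, n_oh)
        mz_obs = mz_true * (1.0 + noise.calibration_ppm * 1e-6) + jitter
        truth.emissions.append(
            PeptideEmission(
                chain_id, start, seq, n_oh, mz_true, mz_obs, intensity, dropped
            )
        )
        if not dropped and noise.mz_min <= mz_obs <= noise.mz_max:
            emitted.append((mz_obs, intensity))

    span = noise.mz_max - noise.mz_min
    n_noise = int(rng.poisson(noise.noise_peak_rate * span / 100.0))
    for _ in range(n_noise):
        pos = noise.mz_min + span * rng.random()
        inten = float(
            np.exp(
                rng.normal(
                    noise.intensity_mu + noise.noise_peak_mu_offset,
                    noise.intensity_sigma,
                )
            )
        )
        emitted.append((pos, inten))

    n = int(np.floor(span / noise.grid_step)) + 1
    mz = noise.mz_min + noise.grid_step * np.arange(n)
    y = noise.baseline_amp * np.exp(-(mz - noise.mz_min) / noise.baseline_decay)
    sigma = noise.fwhm / 2.3548200450309493
    half = 4.0 * sigma
    for pos, inten in emitted:
        lo = max(0, int(np.floor((pos - half - noise.mz_min) / noise.grid_step)))
        hi = min(n, int(np.ceil((pos + half - noise.mz_min) / noise.grid_step)) + 1)
        if lo >= hi:
            continue
        y[lo:hi] += inten * np.exp(-0.5 * ((mz[lo:hi] - pos) / sigma) ** 2)
    if noise.noise_sd:
        y += rng.normal(0.0, noise.noise_sd, size=n)
    np.clip(y, 0.0, None, out=y)
    return Spectrum(sid, mz, y, {"species_id": profile.species_id}), truth


def simulate_cohort(
    profiles: list[SpeciesProfile],
    n_per_species: int | None = None,
    noise: SpectrumNoiseModel = SpectrumNoiseModel(),
    seed: int = 0,
    weights: list[float] | None = None,
    n_total: int | None = None,
    dparams: DigestParams = DigestParams(),
    caps: ModificationCaps = ModificationCaps(),
    base_manifest: TruthManifest | None = None,
) -> tuple[list[Spectrum], TruthManifest]:
    """Simulate a labeled cohort of spectra.

    Either ``n_per_species`` (balanced design) or ``weights`` + ``n_total``
    (species drawn per sample from the composition weights) must be given.
    Returns the spectra and a manifest holding per-sample truth (and the
    planted substitutions of ``base_manifest`` when provided).
    """
    by_id = {p.species_id: p for p in profiles}
    rng = np.random.default_rng(seed)
    if weights is not None:
        if n_total is None:
            raise ValueError("weights require n_total")
        w = np.asarray(weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        order = [p.species_id for p in profiles]
        labels = [
            order[i] for i in rng.choice(len(order), size=n_total, p=w)
        ]
    elif n_per_species is not None:
        labels = [
            p.species_id for p in profiles for _ in range(n_per_species)
        ]
    else:
        raise ValueError("give n_per_species or weights+n_total")

    tables = {
        p.species_id: _peptide_table(p, dparams, noise, caps.max_hydroxylations)
        for p in profiles
    }
    child_seeds = rng.integers(0, 2**31 - 1, size=len(labels))
    manifest = TruthManifest(
        species_ids=tuple(p.species_id for p in profiles),
        substitutions=base_manifest.substitutions if base_manifest else (),
    )
    spectra: list[Spectrum] = []
    for i, (sp, s) in enumerate(zip(labels, child_seeds)):
        sid = f"{sp}_{i:04d}"
        spec, truth = simulate_spectrum(
            by_id[sp],
            noise,
            dparams,
            caps,
            seed=int(s),
            sample_id=sid,
            _table=tables[sp],
        )
        spectra.append(spec)
        manifest.samples[sid] = truth
    return spectra, manifest
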