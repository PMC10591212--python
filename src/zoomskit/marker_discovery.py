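"""Discovery of species-discriminating collagen peptide biomarkers.

Homologous tryptic peptides are paired across species positionally — same
chain, same mature start and end — which is valid for gap-free, length-matched
collagen chains. A pairing becomes a marker when its sequences differ between
at least two species or its presence pattern differs; a marker variant carried
by exactly one species is flagged species-specific. Because MALDI-TOF sees
masses, not sequences, a variant is only *diagnostic* if at least one of its
modification-state masses is separated from every mass attributable to other
species by more than the instrument tolerance; mass-coincident (isobaric)
variants are retained but demoted to supporting-only evidence.

A reference panel for the four Mediterranean ``Epinephelus`` groupers
(E. aeneus, E. costae, E. marginatus, E. caninus) is bundled as package data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from zoomskit.collagen_seq import SpeciesProfile
from zoomskit.digest import DigestParams, Peptide, tryptic_peptides
from zoomskit.masscalc import ModificationCaps, variant_masses

logger = logging.getLogger(__name__)

MALDI_VISIBLE = "MALDI_visible"
LCMSMS_ONLY = "LCMSMS_only"
ABSENT = "absent"

_EVIDENCE_CODES = {"x": MALDI_VISIBLE, "l": LCMSMS_ONLY, "": ABSENT}
_EVIDENCE_TO_CODE = {v: k for k, v in _EVIDENCE_CODES.items()}


@dataclass
class MarkerVariant:
    """One sequence form of a marker with its masses and presence pattern."""

    sequence: str
    masses: tuple[float, ...]
    #: (n_hydroxylations, n_deamidations, n_oxidations) per mass, when computed
    states: tuple[tuple[int, int, int], ...] | None
    #: species_id -> evidence level (MALDI_visible / LCMSMS_only / absent)
    presence: dict[str, str]
    species_specific_for: str | None = None
    #: False when every mass collides (within tol) with another species' mass
    diagnostic: bool = True
    #: per-mass isolation flags (aligned with ``masses``); None when unknown,
    #: in which case the variant-level ``diagnostic`` flag applies to all
    diagnostic_states: tuple[bool, ...] | None = None
    #: species where the MALDI peak exists only because of an isobaric peptide
    isobaric_in: tuple[str, ...] = ()
    note: str = ""

    @property
    def present_in(self) -> tuple[str, ...]:
        return tuple(
            s for s, e in self.presence.items() if e != ABSENT
        )

    @property
    def maldi_visible_in(self) -> tuple[str, ...]:
        return tuple(s for s, e in self.presence.items() if e == MALDI_VISIBLE)


@dataclass
class Marker:
    """All variable peptide forms sharing one positional name."""

    name: str
    chain_id: str
    start: int
    variants: list[MarkerVariant] = field(default_factory=list)

    @property
    def species_specific_for(self) -> str | None:
        hits = {v.species_specific_for for v in self.variants} - {None}
        return hits.pop() if len(hits) == 1 else None


@dataclass
class MarkerPanel:
    """A set of markers over a fixed species list, built at a stated tolerance."""

    species: tuple[str, ...]
    markers: list[Marker]
    tolerance: float = 0.2

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError("species list must be nonempty")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    def marker(self, name: str) -> Marker:
        for m in self.markers:
            if m.name == name:
                return m
        raise KeyError(name)

    def all_variants(self):
        for m in self.markers:
            for v in m.variants:
                yield m, v

    @property
    def n_mass_entries(self) -> int:
        return sum(len(v.masses) for _, v in self.all_variants())


@dataclass(frozen=True)
class IsobaricConflict:
    """Two different sequences whose masses collide within tolerance."""

    marker_a: str
    sequence_a: str
    state_a: tuple[int, int, int] | None
    marker_b: str
    sequence_b: str
    state_b: tuple[int, int, int] | None
    mass_a: float
    mass_b: float

    @property
    def shared_mass(self) -> float:
        return 0.5 * (self.mass_a + self.mass_b)


def discover(
    profiles: list[SpeciesProfile],
    dparams: DigestParams = DigestParams(),
    caps: ModificationCaps = ModificationCaps(),
    tol: float = 0.2,
) -> MarkerPanel:
    """Derive a marker panel from species collagen profiles.

    Digests every chain of every species, pairs peptides across species by
    (chain, mature start, mature end), and emits a marker for each pairing
    whose sequences differ between >= 2 species or whose presence pattern
    differs. Output order is deterministic (chain, start). Evidence defaults
    to MALDI_visible; empirical visibility annotations can be applied
    afterwards.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 taxa to discriminate")
    species = tuple(p.species_id for p in profiles)
    # (chain_id, start, end) -> species_id -> Peptide
    groups: dict[tuple[str, int, int], dict[str, Peptide]] = {}
    # full fingerprint background per species (all peptide sequences)
    sequences_by_species: dict[str, set[str]] = {sp: set() for sp in species}
    for prof in profiles:
        for chain in prof.chains:
            for pep in tryptic_peptides(chain, dparams):
                key = (pep.chain_id, pep.start, pep.end)
                prev = groups.setdefault(key, {}).get(prof.species_id)
                if prev is not None and prev.sequence != pep.sequence:
                    # same span twice within one species cannot happen for a
                    # deterministic digest; guard anyway
                    raise RuntimeError(f"conflicting peptides at {key}")
                groups[key][prof.species_id] = pep
                sequences_by_species[prof.species_id].add(pep.sequence)

    markers: dict[tuple[str, int], Marker] = {}
    for (chain_id, start, end), per_sp in sorted(groups.items()):
        seqs = {sp: p.sequence for sp, p in per_sp.items()}
        distinct = set(seqs.values())
        all_present = len(per_sp) == len(species)
        if all_present and len(distinct) < 2:
            continue  # conserved peptide: no discriminating signal
        name = f"{chain_id} {start}"
        marker = markers.setdefault(
            (chain_id, start), Marker(name=name, chain_id=chain_id, start=start)
        )
        for seq in sorted(distinct):
            carriers = sorted(sp for sp, s in seqs.items() if s == seq)
            mv = variant_masses(seq, caps)
            presence = {
                sp: (MALDI_VISIBLE if sp in carriers else ABSENT) for sp in species
            }
            marker.variants.append(
                MarkerVariant(
                    sequence=seq,
                    masses=tuple(v.mz for v in mv),
                    states=tuple(
                        (v.n_hydroxylations, v.n_deamidations, v.n_oxidations)
                        for v in mv
                    ),
                    presence=presence,
                    species_specific_for=carriers[0] if len(carriers) == 1 else None,
                )
            )
    panel = MarkerPanel(
        species=species,
        markers=[markers[k] for k in sorted(markers)],
        tolerance=tol,
    )
    background = {
        sp: np.sort(
            np.array(
                [v.mz for seq in seqs for v in variant_masses(seq, caps)]
            )
        )
        for sp, seqs in sequences_by_species.items()
    }
    _flag_diagnostic(panel, tol, background)
    return panel


def _min_distance(sorted_masses: np.ndarray, m: float) -> float:
    i = int(np.searchsorted(sorted_masses, m))
    out = np.inf
    for j in (i - 1, i):
        if 0 <= j < len(sorted_masses):
            out = min(out, abs(float(sorted_masses[j]) - m))
    return out


def _flag_diagnostic(
    panel: MarkerPanel,
    tol: float,
    background: dict[str, np.ndarray] | None = None,
    guard: float = 0.05,
) -> None:
    """Mark which masses of each variant are isolated from other species.

    A mass state is diagnostic iff no species outside the variant's presence
    set can produce a peak within ``tol + guard`` of it; the guard band covers
    observation error (calibration residual, centroiding), which can push a
    foreign peak whose theoretical separation is barely above the matching
    tolerance into the match window. With ``background`` (the complete
    enumerated fingerprint of each species, conserved peptides included)
    isolation is checked against every foreign peptide mass; without it,
    against the panel's own masses only. A variant is diagnostic iff any of
    its states is.
    """
    margin = tol + guard
    if background is None:
        entries = [
            (set(v.present_in), v.sequence, mass)
            for _, v in panel.all_variants()
            for mass in v.masses
        ]
    for _, v in panel.all_variants():
        mine = set(v.present_in)
        if not mine:
            v.diagnostic = False
            v.diagnostic_states = tuple(False for _ in v.masses)
            continue
        if background is not None:
            foreign_arrays = [
                arr for sp, arr in background.items() if sp not in mine and arr.size
            ]
            flags = tuple(
                all(_min_distance(arr, m) > margin for arr in foreign_arrays)
                for m in v.masses
            )
        else:
            foreign = np.array(
                [
                    mass
                    for others, seq, mass in entries
                    if seq != v.sequence and not (others <= mine)
                ]
            )
            if foreign.size:
                flags = tuple(
                    bool(np.min(np.abs(foreign - m)) > margin) for m in v.masses
                )
            else:
                flags = tuple(True for _ in v.masses)
        v.diagnostic_states = flags
        v.diagnostic = any(flags)


def isobaric_conflicts(panel: MarkerPanel, tol: float = 0.2) -> list[IsobaricConflict]:
    """All cross-variant mass collisions between different sequences.

    Two identical sequences (e.g. the same peptide carried by two species) are
    the same molecule, not an isobaric pair, and are not reported.
    """
    if not panel.markers:
        return []
    flat = []
    for m, v in panel.all_variants():
        states = v.states if v.states is not None else [None] * len(v.masses)
        for mass, st in zip(v.masses, states):
            flat.append((m.name, v.sequence, st, mass))
    out = []
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            na, sa, sta, ma = flat[i]
            nb, sb, stb, mb = flat[j]
            if sa == sb:
                continue
            if abs(ma - mb) <= tol:
                out.append(IsobaricConflict(na, sa, sta, nb, sb, stb, ma, mb))
    out.sort(key=lambda c: c.shared_mass)
    return out


# --- serialization ---------------------------------------------------------

_BASE_COLS = [
    "name",
    "chain",
    "start",
    "sequence",
    "masses",
    "states",
    "species_specific_for",
    "diagnostic",
    "diagnostic_states",
    "isobaric_in",
    "note",
]


def _fmt_states(states) -> str:
    if states is None:
        return ""
    return ";".join(",".join(str(x) for x in st) for st in states)


def _parse_states(text: str):
    if not text:
        return None
    return tuple(tuple(int(x) for x in st.split(",")) for st in text.split(";"))


def export_panel(panel: MarkerPanel, path) -> None:
    """Write a panel as TSV, one row per marker variant (lossless)."""
    rows = []
    for m, v in panel.all_variants():
        row = {
            "name": m.name,
            "chain": m.chain_id,
            "start": m.start,
            "sequence": v.sequence,
            "masses": "/".join(repr(x) for x in v.masses),
            "states": _fmt_states(v.states),
            "species_specific_for": v.species_specific_for or "",
            "diagnostic": int(v.diagnostic),
            "diagnostic_states": (
                ";".join(str(int(f)) for f in v.diagnostic_states)
                if v.diagnostic_states is not None
                else ""
            ),
            "isobaric_in": ";".join(v.isobaric_in),
            "note": v.note,
        }
        for sp in panel.species:
            code = _EVIDENCE_TO_CODE[v.presence.get(sp, ABSENT)]
            row[sp] = code
        rows.append(row)
    df = pd.DataFrame(rows, columns=_BASE_COLS + list(panel.species))
    with open(path, "w") as fh:
        fh.write(f"# tolerance={panel.tolerance!r}\n")
        df.to_csv(fh, sep="\t", index=False)


def import_panel(path) -> MarkerPanel:
    """Read a panel TSV written by :func:`export_panel` (or hand-curated)."""
    with open(path) as fh:
        first = fh.readline()
        tolerance = 0.2
        if first.startswith("#"):
            if "tolerance=" in first:
                tolerance = float(first.split("tolerance=")[1])
            header_line = fh.readline()
        else:
            header_line = first
        cols = header_line.rstrip("\n").split("\t")
        species = tuple(c for c in cols if c not in _BASE_COLS)
        markers: dict[str, Marker] = {}
        for lineno, line in enumerate(fh, start=3):
            if not line.strip():
                continue
            vals = dict(zip(cols, line.rstrip("\n").split("\t")))
            try:
                name = vals["name"]
                chain = vals["chain"]
                start = int(vals["start"])
                masses = tuple(
                    float(x) for x in vals["masses"].split("/") if x
                )
                presence = {}
                for sp in species:
                    code = vals.get(sp, "").strip()
                    presence[sp] = _EVIDENCE_CODES[code.rstrip("*")]
                iso = tuple(
                    s for s in vals.get("isobaric_in", "").split(";") if s
                ) or tuple(
                    sp for sp in species if vals.get(sp, "").endswith("*")
                )
                ds_text = vals.get("diagnostic_states", "")
                variant = MarkerVariant(
                    sequence=vals["sequence"],
                    masses=masses,
                    states=_parse_states(vals.get("states", "")),
                    presence=presence,
                    species_specific_for=vals.get("species_specific_for") or None,
                    diagnostic=bool(int(vals.get("diagnostic", "1") or 1)),
                    diagnostic_states=(
                        tuple(bool(int(x)) for x in ds_text.split(";"))
                        if ds_text
                        else None
                    ),
                    isobaric_in=iso,
                    note=vals.get("note", ""),
                )
            except (KeyError, ValueError) as err:
                raise ValueError(f"panel row {lineno}: {err}") from err
            marker = markers.setdefault(
                name, Marker(name=name, chain_id=chain, start=start)
            )
            marker.variants.append(variant)
    return MarkerPanel(
        species=species, markers=list(markers.values()), tolerance=tolerance
    )


def reference_panel() -> MarkerPanel:
    """The bundled biomarker panel for four Mediterranean Epinephelus groupers.

    Transcribes the published discriminating-peptide table verbatim, including
    evidence annotations (``l`` = seen in LC-MS/MS only, ``*`` = MALDI peak
    exists via an isobaric peptide) and the COL1a2 568 / 1319.6 anomaly, whose
    printed mass is ~17 Da below the computed [M+H]+ of its printed sequence.
    """
    with resources.as_file(
        resources.files("zoomskit").joinpath("data/grouper_panel.tsv")
    ) as p:
        panel = import_panel(p)
    return panel
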