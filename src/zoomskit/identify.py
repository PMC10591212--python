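"""Marker matching and per-sample taxonomic calls.

A sample is called to species level only when exactly one species has
species-specific marker support and no other species has any; conflicting
specific evidence yields an indeterminate call rather than a majority vote.
Markers demoted for isobaric mass collisions cannot justify a species call on
their own. Samples with only genus-shared marker support are called
genus-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from zoomskit.marker_discovery import (
    LCMSMS_ONLY,
    MALDI_VISIBLE,
    MarkerPanel,
)
from zoomskit.spectra import Peak, PreprocessParams, Spectrum, pick_peaks, preprocess

INDETERMINATE = "indeterminate"
GENUS_LEVEL = "genus_level"


@dataclass(frozen=True)
class MarkerMatch:
    """One theoretical mass state of one marker variant vs the peak list."""

    marker_name: str
    sequence: str
    state: tuple[int, int, int] | None
    theoretical_mz: float
    observed_mz: float | None
    delta: float | None
    matched: bool
    #: species whose MALDI fingerprint is expected to show this variant
    species_support: tuple[str, ...]
    specific_for: str | None
    diagnostic: bool
    #: whether this particular mass state is isolated from other species
    state_diagnostic: bool = True


@dataclass
class MatchResult:
    """All marker-mass vs peak comparisons for one sample."""

    sample_id: str
    records: list[MarkerMatch]
    tolerance: float

    def matched_variants(self) -> dict[tuple[str, str], MarkerMatch]:
        """(marker, sequence) -> best matched record, for matched variants."""
        best: dict[tuple[str, str], MarkerMatch] = {}
        for r in self.records:
            if not r.matched:
                continue
            key = (r.marker_name, r.sequence)
            if key not in best or abs(r.delta) < abs(best[key].delta):
                best[key] = r
        return best


@dataclass(frozen=True)
class CallRules:
    """Decision rules for species calls.

    ``min_specific`` species-specific matches are required for a species call
    (single diagnostic peptides are accepted by default); ``use_lcmsms_only``
    relaxes matching to markers only ever seen in LC-MS/MS data, for
    borderline spectra.
    """

    min_specific: int = 1
    min_shared_for_genus: int = 2
    use_lcmsms_only: bool = False


@dataclass
class Identification:
    """Per-sample taxonomic call with its supporting evidence."""

    sample_id: str
    call: str
    species: str | None = None
    supporting: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    score: int = 0


def match_markers(
    peaks: list[Peak],
    panel: MarkerPanel,
    tol: float = 0.2,
    sample_id: str = "sample",
    rules: CallRules = CallRules(),
) -> MatchResult:
    """Test every panel mass state against the peak list.

    For each theoretical mass the best (smallest |delta|) peak within ``tol``
    is recorded. Variants visible only in LC-MS/MS data are excluded unless
    ``rules.use_lcmsms_only`` is set.
    """
    if not panel.markers:
        raise ValueError("empty marker panel")
    ok_evidence = {MALDI_VISIBLE}
    if rules.use_lcmsms_only:
        ok_evidence.add(LCMSMS_ONLY)
    peak_mz = np.array(sorted(pk.mz for pk in peaks))
    peaks_sorted = sorted(peaks, key=lambda pk: pk.mz)

    def best_peak(mass: float) -> Peak | None:
        # nearest peak by m/z via bisection on the sorted peak list
        i = int(np.searchsorted(peak_mz, mass))
        cand = [j for j in (i - 1, i) if 0 <= j < len(peak_mz)]
        if not cand:
            return None
        j = min(cand, key=lambda j: abs(peak_mz[j] - mass))
        return peaks_sorted[j] if abs(peak_mz[j] - mass) <= tol else None

    records: list[MarkerMatch] = []
    for marker, variant in panel.all_variants():
        support = tuple(
            sp for sp, e in variant.presence.items() if e in ok_evidence
        )
        if not support:
            continue
        states = (
            variant.states
            if variant.states is not None
            else [None] * len(variant.masses)
        )
        diag_states = (
            variant.diagnostic_states
            if variant.diagnostic_states is not None
            else [variant.diagnostic] * len(variant.masses)
        )
        for mass, state, sdiag in zip(variant.masses, states, diag_states):
            best = best_peak(mass)
            records.append(
                MarkerMatch(
                    marker_name=marker.name,
                    sequence=variant.sequence,
                    state=state,
                    theoretical_mz=mass,
                    observed_mz=best.mz if best else None,
                    delta=(best.mz - mass) if best else None,
                    matched=best is not None,
                    species_support=support,
                    specific_for=variant.species_specific_for,
                    diagnostic=variant.diagnostic,
                    state_diagnostic=bool(sdiag),
                )
            )
    return MatchResult(sample_id=sample_id, records=records, tolerance=tol)


def call_species(
    m: MatchResult, rules: CallRules = CallRules()
) -> Identification:
    """Apply the species / genus / indeterminate decision rules.

    A matched variant counts as species-specific evidence only through its
    diagnostic (isolated) mass states; variants matched only at isobaric
    states, and variants demoted entirely, contribute shared support at most.
    """
    by_variant: dict[tuple[str, str], list[MarkerMatch]] = {}
    for r in m.records:
        by_variant.setdefault((r.marker_name, r.sequence), []).append(r)
    specific: dict[str, list[str]] = {}
    shared: list[str] = []
    for (name, seq), recs in by_variant.items():
        if not any(r.matched for r in recs):
            continue
        label = f"{name} [{seq}]"
        rec = recs[0]
        specific_hit = (
            rec.specific_for is not None
            and rec.diagnostic
            and any(r.matched and r.state_diagnostic for r in recs)
        )
        if specific_hit:
            specific.setdefault(rec.specific_for, []).append(label)
        elif len(rec.species_support) >= 2:
            shared.append(label)
    if len(specific) > 1:
        conflicts = sorted(
            f"{sp}: {lab}" for sp, labs in specific.items() for lab in labs
        )
        return Identification(
            m.sample_id,
            INDETERMINATE,
            conflicts=conflicts,
            score=len(shared),
        )
    if len(specific) == 1:
        (sp, labs), = specific.items()
        if len(labs) >= rules.min_specific:
            return Identification(
                m.sample_id,
                f"species:{sp}",
                species=sp,
                supporting=sorted(labs) + sorted(shared),
                score=len(labs) + len(shared),
            )
    if len(shared) >= rules.min_shared_for_genus:
        return Identification(
            m.sample_id, GENUS_LEVEL, supporting=sorted(shared), score=len(shared)
        )
    return Identification(m.sample_id, INDETERMINATE, score=len(shared))


def identify_sample(
    spectrum: Spectrum,
    panel: MarkerPanel,
    pparams: PreprocessParams = PreprocessParams(snr_threshold=5.0),
    tol: float = 0.2,
    rules: CallRules = CallRules(),
) -> Identification:
    """Full per-sample pipeline: preprocess, pick peaks, match, call.

    Peak picking here defaults to the stringent end (5.0) of the conventional
    MALDI S/N range: the automated pipeline has no manual-inspection step, and
    a spurious peak that lands on another species' diagnostic mass triggers
    the conservative conflict rule. Collagen peptide peaks sit far above
    either threshold, so sensitivity is unaffected.
    """
    from zoomskit.spectra import is_centroided

    s = spectrum if is_centroided(spectrum) else preprocess(spectrum, pparams)
    peaks = pick_peaks(s, pparams)
    return call_species(
        match_markers(peaks, panel, tol, spectrum.sample_id, rules), rules
    )


@dataclass
class CohortSummary:
    """Per-group call counts and proportions."""

    table: pd.DataFrame  # columns: group, call, count, proportion

    def species_level_rate(self, group: str | None = None) -> float:
        t = self.table
        if group is not None:
            t = t[t["group"] == group]
        total = t["count"].sum()
        if total == 0:
            return 0.0
        sp = t[t["call"].str.startswith("species:")]["count"].sum()
        return float(sp) / float(total)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def summarize_cohort(
    ids: list[Identification],
    groups: dict[str, str] | None = None,
) -> CohortSummary:
    """Count calls per group; ungrouped samples fall into a single group."""
    rows = []
    for ident in ids:
        g = (groups or {}).get(ident.sample_id, "all")
        rows.append({"group": g, "call": ident.call})
    if not rows:
        return CohortSummary(
            pd.DataFrame(columns=["group", "call", "count", "proportion"])
        )
    df = (
        pd.DataFrame(rows)
        .groupby(["group", "call"])
        .size()
        .rename("count")
        .reset_index()
    )
    df["proportion"] = df["count"] / df.groupby("group")["count"].transform("sum")
    return CohortSummary(df.sort_values(["group", "call"]).reset_index(drop=True))
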