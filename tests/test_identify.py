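"""Marker matching, species-calling rules and cohort summaries."""

import itertools

import pytest

from zoomskit.identify import (
    CallRules,
    Identification,
    call_species,
    match_markers,
    summarize_cohort,
)
from zoomskit.marker_discovery import (
    ABSENT,
    LCMSMS_ONLY,
    MALDI_VISIBLE,
    Marker,
    MarkerPanel,
    MarkerVariant,
)
from zoomskit.spectra import Peak

SPECIES = ("aeneus", "costae", "marginatus", "caninus")


def variant(seq, masses, presence, specific=None, diagnostic=True,
            evidence=MALDI_VISIBLE):
    pres = {sp: (evidence if sp in presence else ABSENT) for sp in SPECIES}
    return MarkerVariant(
        sequence=seq,
        masses=tuple(masses),
        states=tuple((i, 0, 0) for i in range(len(masses))),
        presence=pres,
        species_specific_for=specific,
        diagnostic=diagnostic,
        diagnostic_states=tuple(diagnostic for _ in masses),
    )


def toy_panel():
    markers = [
        Marker(
            "COL1a1 586",
            "COL1a1",
            586,
            [
                variant(
                    "GLTGPLGLPGPAGATGDKGESGPAGPVGPAGAR",
                    (2855.33, 2871.33),
                    {"aeneus"},
                    specific="aeneus",
                ),
                variant(
                    "GLTGPLGLPGPAGATGDKGEPGPAGPVGPGGAR",
                    (2851.34, 2867.34),
                    {"costae", "marginatus", "caninus"},
                ),
            ],
        ),
        Marker(
            "COL1a2 568",
            "COL1a2",
            568,
            [
                variant(
                    "GEAGHRGPDGNAGR",
                    (1350.6,),
                    {"aeneus", "costae", "marginatus", "caninus"},
                )
            ],
        ),
        Marker(
            "COL1a3 934",
            "COL1a3",
            934,
            [
                variant(
                    "GFTGMQGLPGPAGVHGER",
                    (1783.8, 1799.8),
                    {"costae"},
                    specific="costae",
                ),
                variant(
                    "GFTGMQGLPGPAGAHGER",
                    (1755.78,),
                    {"aeneus", "marginatus", "caninus"},
                ),
            ],
        ),
        Marker(
            "COL1a3 271",
            "COL1a3",
            271,
            [
                variant(
                    "GEPGPAGVQGLSGPSGEEGKR",
                    (1965.9,),
                    {"aeneus"},
                    specific="aeneus",
                    evidence=LCMSMS_ONLY,
                )
            ],
        ),
    ]
    return MarkerPanel(species=SPECIES, markers=markers)


def peak(mz):
    return Peak(mz, 100.0, 50.0)


class TestMatching:
    def test_both_ladder_states_matched(self):
        m = match_markers([peak(2855.31), peak(2871.35)], toy_panel(), 0.2)
        hits = [r for r in m.records if r.matched]
        assert {round(r.theoretical_mz, 2) for r in hits} == {2855.33, 2871.33}
        assert hits[0].delta == pytest.approx(-0.02, abs=1e-9)

    def test_empty_peak_list_matches_nothing(self):
        m = match_markers([], toy_panel(), 0.2)
        assert all(not r.matched for r in m.records)

    def test_just_outside_tolerance_unmatched(self):
        m = match_markers([peak(2855.6)], toy_panel(), 0.2)
        assert all(not r.matched for r in m.records)

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ValueError):
            match_markers([peak(1000.0)], MarkerPanel(SPECIES, []), 0.2)

    def test_lcmsms_only_markers_excluded_by_default(self):
        m = match_markers([peak(1965.9)], toy_panel(), 0.2)
        assert all(r.theoretical_mz != 1965.9 for r in m.records)
        relaxed = match_markers(
            [peak(1965.9)], toy_panel(), 0.2, rules=CallRules(use_lcmsms_only=True)
        )
        assert any(r.matched and r.theoretical_mz == 1965.9 for r in relaxed.records)

    def test_tightening_tolerance_never_creates_matches(self):
        peaks = [peak(x) for x in (1350.55, 1755.9, 2851.2, 2855.5)]
        matched = {}
        for tol in (0.05, 0.1, 0.2, 0.4):
            m = match_markers(peaks, toy_panel(), tol)
            matched[tol] = {
                (r.marker_name, r.sequence, r.theoretical_mz)
                for r in m.records
                if r.matched
            }
        assert matched[0.05] <= matched[0.1] <= matched[0.2] <= matched[0.4]

    def test_brute_force_assignment_oracle(self):
        """Best-match selection agrees with exhaustive nearest-peak search."""
        panel = toy_panel()
        masses = [
            (m.name, v.sequence, mz)
            for m, v in panel.all_variants()
            for mz in v.masses
            if any(e == MALDI_VISIBLE for e in v.presence.values())
        ]
        peak_sets = [
            [],
            [peak(1350.62)],
            [peak(x) for x in (1350.5, 1350.7, 2851.3, 2867.2, 9999.0)],
            [peak(x) for x in (1783.75, 1783.9, 1799.81, 2855.4)],
        ]
        for peaks_ in peak_sets:
            m = match_markers(peaks_, panel, 0.2)
            for r in m.records:
                cands = [
                    p for p in peaks_ if abs(p.mz - r.theoretical_mz) <= 0.2
                ]
                if not cands:
                    assert not r.matched
                else:
                    best = min(cands, key=lambda p: abs(p.mz - r.theoretical_mz))
                    assert r.matched and r.observed_mz == best.mz


class TestCalling:
    def test_specific_plus_shared_gives_species(self):
        peaks = [peak(2855.33), peak(1350.6), peak(1755.78)]
        ident = call_species(match_markers(peaks, toy_panel(), 0.2))
        assert ident.call == "species:aeneus"
        assert ident.species == "aeneus"
        assert any("COL1a1 586" in s for s in ident.supporting)

    def test_only_shared_markers_gives_genus(self):
        peaks = [peak(1350.6), peak(1755.78)]
        ident = call_species(match_markers(peaks, toy_panel(), 0.2))
        assert ident.call == "genus_level"

    def test_conflicting_specific_markers_force_indeterminate(self):
        peaks = [peak(2855.33), peak(1783.8)]  # aeneus- and costae-specific
        ident = call_species(match_markers(peaks, toy_panel(), 0.2))
        assert ident.call == "indeterminate"
        assert ident.conflicts

    def test_no_matches_is_indeterminate(self):
        ident = call_species(match_markers([], toy_panel(), 0.2))
        assert ident.call == "indeterminate"

    def test_demoted_variant_cannot_justify_species_call(self):
        panel = toy_panel()
        for _, v in panel.all_variants():
            if v.species_specific_for == "aeneus" and v.masses[0] == 2855.33:
                v.diagnostic = False
                v.diagnostic_states = (False, False)
        peaks = [peak(2855.33), peak(1350.6), peak(1755.78)]
        ident = call_species(match_markers(peaks, panel, 0.2))
        assert ident.call == "genus_level"

    def test_added_shared_marker_never_flips_species(self):
        base = [peak(2855.33)]
        first = call_species(match_markers(base, toy_panel(), 0.2))
        more = call_species(
            match_markers(base + [peak(1350.6), peak(1755.78)], toy_panel(), 0.2)
        )
        assert first.species == more.species == "aeneus"
        assert more.score >= first.score


class TestCohortSummary:
    @staticmethod
    def _ident(i, call, species=None):
        return Identification(f"s{i}", call, species=species)

    def test_proportions_sum_to_one_per_group(self):
        ids = [
            self._ident(0, "species:aeneus", "aeneus"),
            self._ident(1, "species:aeneus", "aeneus"),
            self._ident(2, "genus_level"),
            self._ident(3, "indeterminate"),
            self._ident(4, "species:costae", "costae"),
        ]
        groups = {"s0": "bronze", "s1": "bronze", "s2": "bronze",
                  "s3": "iron", "s4": "iron"}
        summary = summarize_cohort(ids, groups)
        sums = summary.table.groupby("group")["proportion"].sum()
        assert all(abs(x - 1.0) < 1e-9 for x in sums)
        assert summary.species_level_rate("bronze") == pytest.approx(2 / 3)

    def test_species_level_rate_like_published_cohort(self):
        """84 species-level calls out of 94 gives the 89% headline rate."""
        ids = [
            self._ident(i, "species:aeneus", "aeneus") for i in range(84)
        ] + [self._ident(84 + i, "indeterminate") for i in range(10)]
        summary = summarize_cohort(ids)
        assert summary.species_level_rate() == pytest.approx(84 / 94, abs=1e-9)

    def test_single_sample_proportions_are_unit(self):
        summary = summarize_cohort([self._ident(0, "genus_level")])
        assert list(summary.table["proportion"]) == [1.0]

    def test_empty_input_empty_summary(self):
        assert summarize_cohort([]).table.empty
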