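"""Design-ensemble loading, dedup, frequencies, enrichment and ranking."""

import numpy as np
import pytest

import nacscore as ns
from nacscore.enrichment import DesignEnsemble, DesignRecord
from nacscore.errors import ConfigurationError
from nacscore.synthetic import generate_design_library, make_position_distributions

POSITIONS = (76, 80, 95)


def _record(design_id, seq, energy):
    return DesignRecord(design_id=design_id,
                        residues=dict(zip(POSITIONS, seq)), energy=energy)


def _ensemble(records, mode="pro_S", deduped=False):
    return DesignEnsemble(mode=mode, designable_positions=POSITIONS,
                          records=list(records), deduped=deduped)


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class TestLoadDesigns:
    HEADER = "design_id\t76\t80\t95\tenergy\n"

    def test_small_fixture(self, tmp_path):
        p = tmp_path / "designs.tsv"
        rows = [f"d{i}\tF\tP\tT\t{130.0 + i}\n" for i in range(5)]
        p.write_text(self.HEADER + "".join(rows))
        ens = ns.load_designs(p, "pro_S")
        assert len(ens) == 5
        assert ens.designable_positions == (76, 80, 95)
        assert ens.records[0].residues == {76: "F", 80: "P", 95: "T"}
        assert not ens.deduped

    def test_invalid_amino_acid_reports_line(self, tmp_path):
        p = tmp_path / "designs.tsv"
        p.write_text(self.HEADER + "d0\tF\tX\tT\t130\n")
        with pytest.raises(ConfigurationError, match="line 2"):
            ns.load_designs(p, "pro_S")

    def test_non_numeric_energy_rejected(self, tmp_path):
        p = tmp_path / "designs.tsv"
        p.write_text(self.HEADER + "d0\tF\tP\tT\tlow\n")
        with pytest.raises(ConfigurationError, match="energy"):
            ns.load_designs(p, "pro_S")

    def test_header_only_file_is_valid_empty_ensemble(self, tmp_path):
        p = tmp_path / "designs.tsv"
        p.write_text(self.HEADER)
        ens = ns.load_designs(p, "pro_S")
        assert len(ens) == 0

    def test_roundtrip_through_save(self, tmp_path):
        ens = _ensemble([_record("a", "FPT", -1.5), _record("b", "FAW", -2.5)])
        p = tmp_path / "out.tsv"
        ns.save_designs(ens, p)
        loaded = ns.load_designs(p, "pro_S")
        assert [r.residues for r in loaded.records] == \
            [r.residues for r in ens.records]
        assert [r.energy for r in loaded.records] == [-1.5, -2.5]


# ---------------------------------------------------------------------------
# dedup
# ---------------------------------------------------------------------------

class TestDedupeLowestEnergy:
    def test_keeps_minimum_energy_copy(self):
        ens = _ensemble([_record("a1", "FPT", -10.0), _record("a2", "FPT", -8.0),
                         _record("b", "FAW", -9.0)])
        out = ns.dedupe_lowest_energy(ens)
        assert out.deduped
        assert [(r.design_id, r.energy) for r in out.records] == \
            [("a1", -10.0), ("b", -9.0)]

    def test_all_distinct_unchanged_membership(self):
        ens = _ensemble([_record("a", "FPT", -1.0), _record("b", "FAW", -2.0)])
        out = ns.dedupe_lowest_energy(ens)
        assert {r.design_id for r in out.records} == {"a", "b"}

    def test_idempotent_and_survivors_are_class_minima(self, rng):
        aas = list("ACDEF")
        records = [
            _record(f"d{i}", "".join(rng.choice(aas, size=3)),
                    float(rng.normal(0, 2)))
            for i in range(100)
        ]
        ens = _ensemble(records)
        once = ns.dedupe_lowest_energy(ens)
        twice = ns.dedupe_lowest_energy(once)
        assert [r.design_id for r in once.records] == \
            [r.design_id for r in twice.records]
        assert len(once) <= len(ens)
        # brute force: every survivor carries the minimum of its class
        for rec in once.records:
            key = rec.sequence_key(POSITIONS)
            class_min = min(r.energy for r in records
                            if r.sequence_key(POSITIONS) == key)
            assert rec.energy == class_min
        energies = [r.energy for r in once.records]
        assert energies == sorted(energies)

    def test_synthetic_multiplicity_1748_to_251(self):
        """Duplicate injection at the historical 1748-to-251 ratio dedups exactly."""
        positions = list(range(1, 15))
        dists = make_position_distributions(positions)
        ens_s, _, info = generate_design_library(
            positions, dists, dists, n=251, duplicate_rate=1497 / 251,
            seed=99, unique_base=True)
        assert len(ens_s) == 1748
        out = ns.dedupe_lowest_energy(ens_s)
        assert len(out) == 251
        survivor_ids = {r.design_id for r in out.records}
        assert survivor_ids.isdisjoint(info["pro_S"]["duplicate_ids"])


# ---------------------------------------------------------------------------
# frequencies and enrichment
# ---------------------------------------------------------------------------

class TestFrequencies:
    def test_half_half(self):
        ens = _ensemble([_record("a", "APT", -4), _record("b", "APT", -3),
                         _record("c", "VPT", -2), _record("d", "VPT", -1)])
        # make sequences distinct at position 95 so dedup keeps all four
        ens.records[1] = _record("b", "APW", -3)
        ens.records[3] = _record("d", "VPW", -1)
        freq = ns.frequency_table(ns.dedupe_lowest_energy(ens))
        assert freq.freq.loc[76, "A"] == pytest.approx(0.5)
        assert freq.freq.loc[76, "V"] == pytest.approx(0.5)

    def test_single_design_all_ones(self):
        freq = ns.frequency_table(_ensemble([_record("a", "FPT", 0.0)],
                                            deduped=True))
        assert freq.freq.loc[76, "F"] == 1.0
        assert freq.freq.loc[95, "T"] == 1.0

    def test_requires_dedup(self):
        with pytest.raises(ValueError, match="dedup"):
            ns.frequency_table(_ensemble([_record("a", "FPT", 0.0)]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ns.frequency_table(_ensemble([], deduped=True))

    def test_rows_normalized(self, rng):
        records = [_record(f"d{i}", "".join(rng.choice(list("FAWPTV"), size=3)),
                           float(i)) for i in range(50)]
        freq = ns.frequency_table(ns.dedupe_lowest_energy(_ensemble(records)))
        assert np.allclose(freq.freq.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_frequency_recovered_within_binomial_bound(self):
        positions = [76, 80, 95]
        dist = make_position_distributions(positions, biases={95: {"F": 0.4}})
        ens_s, _, _ = generate_design_library(positions, dist, dist, n=2000,
                                              duplicate_rate=0.0, seed=21)
        ens_s.deduped = True           # duplicate-free by construction
        freq = ns.frequency_table(ens_s)
        tol = 3 * np.sqrt(0.4 * 0.6 / 2000)
        assert freq.freq.loc[95, "F"] == pytest.approx(0.4, abs=tol)


class TestEnrichment:
    def _freqs(self, fa, fv):
        recs_s = [_record(f"s{i}", aa + "PT", float(i))
                  for i, aa in enumerate(["A"] * 5 + ["V"] * 5)]
        recs_r = [_record(f"r{i}", aa + "PT", float(i))
                  for i, aa in enumerate(["A"] * 2 + ["V"] * 8)]
        # perturb position 95 to keep sequences distinct
        for recs in (recs_s, recs_r):
            for j, r in enumerate(recs):
                r.residues[95] = "ACDEFGHIKL"[j]
        fs = ns.frequency_table(ns.dedupe_lowest_energy(_ensemble(recs_s)))
        fr = ns.frequency_table(ns.dedupe_lowest_energy(
            _ensemble(recs_r, mode="pro_R")))
        return fs, fr

    def test_pe_arithmetic(self):
        fs, fr = self._freqs(0.5, 0.2)
        pe = ns.percentage_enrichment(fs, fr)
        assert pe.pe.loc[76, "A"] == pytest.approx(100 * (0.5 - 0.2))
        assert pe.pe.loc[76, "G"] == 0.0       # absent from both

    def test_pe_antisymmetric(self):
        fs, fr = self._freqs(0.5, 0.2)
        pe_s = ns.percentage_enrichment(fs, fr).pe
        pe_r = ns.percentage_enrichment(fr, fs).pe
        assert np.allclose(pe_s.values, -pe_r.values, atol=1e-12)
        assert np.all(np.abs(pe_s.values) <= 100.0)

    def test_position_mismatch_rejected(self):
        fs, _ = self._freqs(0.5, 0.2)
        other = ns.frequency_table(DesignEnsemble(
            mode="pro_R", designable_positions=(1, 2, 3),
            records=[DesignRecord("x", {1: "A", 2: "A", 3: "A"}, 0.0)],
            deduped=True))
        with pytest.raises(ValueError, match="position"):
            ns.percentage_enrichment(fs, other)

    def test_exclusive_substitutions_strict_zero_rule(self):
        recs_s = [_record(f"s{i}", "FP" + "ACDEFGHIKLMNPQRSTVWY"[i], -float(i))
                  for i in range(20)]
        recs_r = [_record(f"r{i}", "VP" + "ACDEFGHIKLMNPQRSTVWY"[i], -float(i))
                  for i in range(20)]
        fs = ns.frequency_table(ns.dedupe_lowest_energy(_ensemble(recs_s)))
        fr = ns.frequency_table(ns.dedupe_lowest_energy(
            _ensemble(recs_r, mode="pro_R")))
        ex = ns.exclusive_substitutions(fs, fr, min_count=3)
        assert (76, "F", "pro_S") in ex
        assert (76, "V", "pro_R") in ex
        # a single stray occurrence on the other side kills exclusivity
        recs_r.append(_record("stray", "FPA", 100.0))
        recs_r[-1].residues[95] = "Y"
        fr2 = ns.frequency_table(ns.dedupe_lowest_energy(
            _ensemble(recs_r, mode="pro_R")))
        ex2 = ns.exclusive_substitutions(fs, fr2, min_count=3)
        assert (76, "F", "pro_S") not in ex2
        # min_count above every count -> nothing
        assert ns.exclusive_substitutions(fs, fr, min_count=1000) == []

    def test_comparative_identical_tables_all_zero_and_tied(self):
        fs, _ = self._freqs(0.5, 0.2)
        comp = ns.comparative_table(fs, fs)
        assert (comp["pe_S"] == 0).all()
        assert comp["tie_S"].all()

    def test_rank_planted_library_top_hit(self):
        positions = [76, 80, 95]
        dist_s = make_position_distributions(positions, biases={95: {"F": 0.40}})
        dist_r = make_position_distributions(positions, biases={95: {"F": 0.02}})
        ens_s, ens_r, _ = generate_design_library(positions, dist_s, dist_r,
                                                  n=1000, duplicate_rate=0.05,
                                                  seed=31)
        fs = ns.frequency_table(ns.dedupe_lowest_energy(ens_s))
        fr = ns.frequency_table(ns.dedupe_lowest_energy(ens_r))
        report = ns.rank_candidates(fs, fr, min_count=3, top_k=5)
        top = report.table.iloc[0]
        assert (top["position"], top["aa"]) == (95, "F")
        single = ns.rank_candidates(fs, fr, top_k=1)
        assert len(single.table) == 1


# ---------------------------------------------------------------------------
# generator bookkeeping
# ---------------------------------------------------------------------------

class TestGenerateDesignLibrary:
    def test_zero_duplicate_rate(self):
        positions = [76, 80]
        dists = make_position_distributions(positions)
        ens_s, ens_r, info = generate_design_library(positions, dists, dists,
                                                     n=50, duplicate_rate=0.0,
                                                     seed=1)
        assert len(ens_s) == 50 and len(ens_r) == 50
        assert info["pro_S"]["duplicate_ids"] == []

    def test_duplicates_have_higher_energy_than_source(self):
        positions = [76, 80]
        dists = make_position_distributions(positions)
        ens_s, _, info = generate_design_library(positions, dists, dists, n=100,
                                                 duplicate_rate=0.3, seed=2,
                                                 unique_base=True)
        by_id = {r.design_id: r for r in ens_s.records}
        for dup, src in info["pro_S"]["duplicate_sources"].items():
            assert by_id[dup].energy > by_id[src].energy
            assert by_id[dup].residues == by_id[src].residues

    def test_dedupe_removes_exactly_injected_copies(self):
        positions = [76, 80, 95, 179]
        dists = make_position_distributions(positions)
        ens_s, _, info = generate_design_library(positions, dists, dists, n=200,
                                                 duplicate_rate=0.25, seed=3,
                                                 unique_base=True)
        out = ns.dedupe_lowest_energy(ens_s)
        assert len(out) == 200
        assert {r.design_id for r in out.records}.isdisjoint(
            info["pro_S"]["duplicate_ids"])

    def test_invalid_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_design_library([76], {76: {"A": 0.5}}, {76: {"A": 0.5}},
                                    n=10)
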