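"""Parsimony allele reconstruction: seeding, pairs, polyploids, reports."""

from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctmarker.phasing import (
    clark_resolve,
    complement_for,
    explain_polyploid,
    name_alleles,
    phase_report,
    seed_pool,
)
from ctmarker.polymorphism import GenotypePattern, binary_encode, find_polymorphic_sites
from ctmarker.simulate import simulate_species_panel
from _helpers import truth_binaries


def _pat(sample_id, codes, ploidy=2):
    return GenotypePattern(sample_id, codes, ploidy)


class TestSeedPool:
    def test_two_homozygotes(self):
        pool = seed_pool([_pat("a", "11"), _pat("b", "00")])
        assert sorted(a.binary for a in pool) == ["00", "11"]

    def test_single_snp_rule(self):
        pool = seed_pool([_pat("a", "1H")])
        assert sorted(a.binary for a in pool) == ["10", "11"]

    def test_multi_het_not_seedable(self):
        with pytest.warns(UserWarning, match="empty seed pool"):
            assert seed_pool([_pat("a", "HH")]) == []

    def test_seeded_alleles_exist_in_truth(self, diploid_panel):
        aln = diploid_panel.alignment()
        sites = find_polymorphic_sites(aln, diploid_panel.species)
        patterns = [binary_encode(sites, s.sequence) for s in diploid_panel.samples]
        truth = set(truth_binaries(diploid_panel, sites))
        for allele in seed_pool(patterns):
            assert allele.binary in truth


class TestClarkResolve:
    def test_complement_rule(self):
        asg, pool = clark_resolve([_pat("a", "HH")], ["10"])
        assert asg[0].status == "resolved"
        assert asg[0].alleles == ("01", "10")
        assert "01" in {a.binary for a in pool}

    def test_homozygote_self_pair(self):
        asg, _ = clark_resolve([_pat("a", "11")])
        assert asg[0].status == "resolved"
        assert asg[0].alleles == ("11", "11")

    def test_ambiguous_two_pairs(self):
        asg, _ = clark_resolve([_pat("a", "HH")], ["10", "11"])
        assert asg[0].status == "ambiguous"
        assert asg[0].candidate_sets == (("00", "11"), ("01", "10"))

    def test_unresolved_without_consistent_allele(self):
        asg, _ = clark_resolve([_pat("a", "HH")], ["00"])
        # 00 is consistent (H sites are free), so this resolves; use 0/1 clash
        asg, _ = clark_resolve([_pat("a", "1H")], ["01"])
        assert asg[0].status == "unresolved"

    def test_pool_only_grows(self):
        seeds = ["11", "00"]
        _, pool = clark_resolve([_pat("a", "1H"), _pat("b", "HH")], seeds)
        binaries = {a.binary for a in pool}
        assert set(seeds) <= binaries

    def test_soundness_of_resolved_pairs(self, diploid_panel):
        aln = diploid_panel.alignment()
        sites = find_polymorphic_sites(aln, diploid_panel.species)
        patterns = [binary_encode(sites, s.sequence) for s in diploid_panel.samples]
        asg, _ = clark_resolve(patterns, seed_pool(patterns))
        by_id = {p.sample_id: p for p in patterns}
        for a in asg:
            if a.status != "resolved":
                continue
            x, y = a.alleles
            for bit_x, bit_y, code in zip(x, y, by_id[a.sample_id].codes):
                if code in "01":
                    assert bit_x == bit_y == code
                elif code == "H":
                    assert {bit_x, bit_y} == {"0", "1"}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_full_recovery_under_clark_condition(self, seed):
        """With >=1 homozygote per allele, resolution is complete and exact."""
        panel = simulate_species_panel(n_samples=20, n_alleles=5, seed=seed)
        aln = panel.alignment()
        sites = find_polymorphic_sites(aln, panel.species)
        patterns = [binary_encode(sites, s.sequence) for s in panel.samples]
        asg, _ = clark_resolve(patterns, seed_pool(patterns))
        binaries = truth_binaries(panel, sites)
        assert all(a.status == "resolved" for a in asg)
        for a in asg:
            truth = tuple(sorted(binaries[i] for i in panel.genotypes[a.sample_id]))
            assert tuple(sorted(a.alleles)) == truth


@given(
    st.text(alphabet="01H", min_size=1, max_size=12).filter(lambda c: "H" in c)
)
@settings(derandomize=True)
def test_complement_involution(codes):
    allele = codes.replace("H", "0")
    partner = complement_for(allele, codes)
    assert complement_for(partner, codes) == allele
    assert partner != allele


class TestExplainPolyploid:
    def test_tetraploid_single_allele(self):
        asg = explain_polyploid(_pat("a", "11", 4), ["11"], 4)
        assert (asg.status, asg.alleles) == ("resolved", ("11",))

    def test_minimal_explanation_preferred(self):
        asg = explain_polyploid(_pat("a", "HH", 6), ["10", "01", "11"], 6)
        assert asg.status == "resolved"
        assert asg.alleles == ("01", "10")

    def test_ambiguous_minimal_sets(self):
        asg = explain_polyploid(_pat("a", "HH", 4), ["10", "01", "11", "00"], 4)
        assert asg.status == "ambiguous"
        assert ("00", "11") in asg.candidate_sets
        assert ("01", "10") in asg.candidate_sets

    def test_unresolved_when_uncoverable(self):
        asg = explain_polyploid(_pat("a", "HH", 4), ["11"], 4)
        assert asg.status == "unresolved"

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_agrees_with_bruteforce_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        for _ in range(60):
            n_sites = int(rng.integers(1, 7))
            pool = sorted(
                {
                    "".join(rng.choice(["0", "1"], n_sites))
                    for _ in range(int(rng.integers(1, 9)))
                }
            )
            codes = "".join(rng.choice(["0", "1", "H"], n_sites))
            ploidy = int(rng.choice([4, 6]))
            got = explain_polyploid(_pat("a", codes, ploidy), pool, ploidy)
            expected = _oracle_minimal_sets(codes, pool, ploidy)
            if len(expected) == 1:
                assert (got.status, got.alleles) == ("resolved", expected[0])
            elif expected:
                assert got.status == "ambiguous"
                assert tuple(sorted(expected)) == got.candidate_sets
            else:
                assert got.status == "unresolved"

    def test_max_alleles_per_plant_bounded(self, small_dataset):
        truth = small_dataset.truth
        for sid, geno in truth.genotypes.items():
            ploidy = next(
                s.ploidy for s in small_dataset.samples if s.sample_id == sid
            )
            assert len(set(geno)) <= ploidy


def _oracle_minimal_sets(codes, pool, ploidy):
    """Plain enumeration of all minimal explaining subsets."""
    def explains(subset):
        for i, code in enumerate(codes):
            values = {a[i] for a in subset}
            want = {"0": {"0"}, "1": {"1"}, "H": {"0", "1"}}[code]
            if values != want:
                return False
        return True

    for k in range(1, ploidy + 1):
        sols = [
            tuple(sorted(s)) for s in combinations(pool, k) if explains(s)
        ]
        if sols:
            return sorted(set(sols))
    return []


class TestReporting:
    def test_all_homozygote_report(self):
        asg, _ = clark_resolve([_pat("a", "11"), _pat("b", "00")])
        df = phase_report({"sp": asg})
        row = df.iloc[0]
        assert (row.n_genotypes, row.n_homozygotes, row.n_heterozygotes) == (2, 2, 0)
        assert row.n_unique_alleles == 2

    def test_single_het_pair_report(self):
        asg, _ = clark_resolve([_pat("a", "H")], ["1"])
        df = phase_report({"sp": asg})
        row = df.iloc[0]
        assert (row.n_unique_alleles, row.n_heterozygotes) == (2, 1)
        assert row.max_alleles_per_plant == 2

    def test_report_matches_ground_truth(self, diploid_panel):
        panel = diploid_panel
        aln = panel.alignment()
        sites = find_polymorphic_sites(aln, panel.species)
        patterns = [binary_encode(sites, s.sequence) for s in panel.samples]
        asg, _ = clark_resolve(patterns, seed_pool(patterns))
        df = phase_report({panel.species: asg})
        row = df.iloc[0]
        genos = panel.genotypes.values()
        assert row.n_genotypes == len(panel.samples)
        assert row.n_homozygotes == sum(len(set(g)) == 1 for g in genos)
        assert row.n_heterozygotes == sum(len(set(g)) > 1 for g in genos)
        carried = {i for g in genos for i in g}
        assert row.n_unique_alleles == len(carried)

    def test_allele_naming_by_frequency(self):
        asg, _ = clark_resolve(
            [_pat("a", "11"), _pat("b", "11"), _pat("c", "1H")]
        )
        names = name_alleles(asg)
        assert names["11"] == "A"  # most frequent
        assert names["10"] == "B"
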