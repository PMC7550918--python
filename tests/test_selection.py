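import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from resicor import (
    DomainError,
    PipelineError,
    SelectionConfig,
    apply_site_constraint,
    parse_residues,
    residue_correlation_profile,
    run_paper_pipeline,
    select_by_sign,
)
from resicor.correlation import ResidueCorrelationProfile
from resicor.residues import ResidueID
from tests.conftest import random_dataset


def profile_of(paper):
    return residue_correlation_profile(paper.energy_matrix, paper.activities)


class TestSelectBySign:
    def test_negative_rule_excludes_val509(self, paper):
        """The rule as written keeps the six negative-r residues; VAL509
        (printed r = +0.20) is excluded, unlike in the published cluster."""
        selected = select_by_sign(profile_of(paper), SelectionConfig(sign="negative"))
        assert {str(r) for r in selected} == {
            "GLN178", "SER339", "TYR341", "ARG499", "PHE504", "ALA513",
        }

    def test_positive_rule(self, paper):
        selected = select_by_sign(profile_of(paper), SelectionConfig(sign="positive"))
        assert {str(r) for r in selected} == {
            "VAL509", "VAL335", "LEU338", "TYR371", "ILE503", "SER516",
        }

    def test_all_positive_profile_gives_empty_negative_selection(self):
        prof = ResidueCorrelationProfile(
            r={ResidueID.parse("ALA1"): 0.5, ResidueID.parse("GLY2"): 0.1}, n=5
        )
        assert select_by_sign(prof, SelectionConfig(sign="negative")) == frozenset()

    def test_exact_zero_boundary(self):
        prof = ResidueCorrelationProfile(r={ResidueID.parse("ALA1"): 0.0}, n=5)
        assert select_by_sign(prof, SelectionConfig(sign="negative", strict_zero=True)) == frozenset()
        assert select_by_sign(prof, SelectionConfig(sign="negative", strict_zero=False)) == frozenset(
            parse_residues(["ALA1"])
        )

    @settings(derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10**6))
    def test_sign_partition_property(self, seed):
        """negative ∪ positive ∪ {zero, undefined} covers all residues."""
        rng = np.random.default_rng(seed)
        E, A = random_dataset(rng, n_residues=5)
        prof = residue_correlation_profile(E, A)
        neg = select_by_sign(prof, SelectionConfig(sign="negative"))
        pos = select_by_sign(prof, SelectionConfig(sign="positive"))
        zero = {res for res, r in prof.r.items() if r == 0}
        assert neg | pos | zero | set(prof.undefined) == set(E.residues)
        assert not neg & pos


class TestSiteConstraint:
    def test_published_sites_partition_canonical_cluster(self, paper):
        per_site = apply_site_constraint(paper.canonical_cluster, paper.sites)
        assert {str(r) for r in per_site["Site-1"]} == {"PHE504", "VAL509"}
        assert {str(r) for r in per_site["Site-2"]} == {"GLN178", "SER339", "ARG499"}
        assert {str(r) for r in per_site["Site-3"]} == {"TYR341", "ALA513"}
        assert per_site["unassigned"] == frozenset()

    def test_empty_selection_maps_to_empty_sites(self, paper):
        per_site = apply_site_constraint(frozenset(), paper.sites)
        assert all(v == frozenset() for v in per_site.values())

    def test_residue_outside_every_site_is_unassigned(self, paper):
        stray = parse_residues(["LEU338"])
        per_site = apply_site_constraint(stray, paper.sites)
        assert per_site["unassigned"] == frozenset(stray)


class TestPipeline:
    def test_canonical_override_reproduces_published_r(self, paper):
        result = run_paper_pipeline(
            paper.energy_matrix, paper.activities,
            SelectionConfig(overrides=paper.canonical_cluster),
        )
        assert result.cluster.r == pytest.approx(-0.60, abs=0.03)
        assert result.final_cluster == paper.canonical_cluster

    def test_sign_rule_six_residue_cluster(self, paper):
        """The rule as written yields a 6-residue cluster (no VAL509) whose
        cumulative-energy correlation is -0.650 (regression pin)."""
        result = run_paper_pipeline(
            paper.energy_matrix, paper.activities, SelectionConfig(site_map=paper.sites)
        )
        assert {str(r) for r in result.final_cluster} == {
            "GLN178", "SER339", "TYR341", "ARG499", "PHE504", "ALA513",
        }
        assert result.cluster.r == pytest.approx(-0.6502, abs=1e-3)

    def test_singleton_override_matches_profile(self, paper):
        result = run_paper_pipeline(
            paper.energy_matrix, paper.activities,
            SelectionConfig(overrides=frozenset(parse_residues(["TYR341"]))),
        )
        assert result.cluster.r == result.profile["TYR341"]

    def test_override_equals_direct_cluster_correlation(self, paper):
        from resicor import cluster_correlation

        direct = cluster_correlation(paper.energy_matrix, paper.canonical_cluster, paper.activities)
        piped = run_paper_pipeline(
            paper.energy_matrix, paper.activities,
            SelectionConfig(overrides=paper.canonical_cluster),
        )
        assert piped.cluster.r == direct.r
        assert piped.cluster.per_compound_sum.equals(direct.per_compound_sum)

    def test_empty_selection_raises_pipeline_error(self, toy):
        E, y = toy
        sub = E.subset(parse_residues(["LEU2"]))  # only a positive-r residue
        with pytest.raises(PipelineError, match="overrides"):
            run_paper_pipeline(sub, y, SelectionConfig(sign="negative"))

    def test_report_is_deterministic(self, paper):
        cfg = SelectionConfig(overrides=paper.canonical_cluster, site_map=paper.sites)
        rep1 = run_paper_pipeline(paper.energy_matrix, paper.activities, cfg).report()
        rep2 = run_paper_pipeline(paper.energy_matrix, paper.activities, cfg).report()
        assert json.dumps(rep1, sort_keys=False) == json.dumps(rep2, sort_keys=False)

    def test_empty_overrides_rejected(self):
        with pytest.raises(DomainError):
            SelectionConfig(overrides=frozenset())
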