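"""Corpus screening, SSBOND harvesting, absence validation and aggregation."""

import pytest

from cystmine.fixtures import BondState, CystineSpec, EnsembleSpec, StructureSpec, generate_structure
from cystmine.geometry import CystineGeometry
from cystmine.mapping import ChainMapping
from cystmine.mining import (
    BondObservation,
    aggregate,
    assess_absence,
    harvest_bonds,
    length_filter,
    screen_structure,
)
from cystmine.pdbfile import SSBondRecord, StructureModel


def _geometry(d=2.04):
    return CystineGeometry(
        chi1=-60, chi2=-60, chi3=-90, chi2p=-60, chi1p=-60,
        alpha1=104, alpha2=104, d=d, dse=2.51,
    )


SEQ = "A" * 14 + "C" + "A" * 19 + "C" + "A" * 25  # C at 15 and 35, length 60


def _ensemble(states, pdb_ids=None, **kwargs):
    structures = []
    for k, state in enumerate(states):
        structures.append(
            StructureSpec(
                pdb_id=(pdb_ids or [f"{k + 1:04d}" for k in range(len(states))])[k],
                resolution=1.8,
                bond_states={(15, 35): state},
                **kwargs,
            )
        )
    return EnsembleSpec(accession="P1", sequence=SEQ, structures=structures)


def _model_and_mapping(state, **kwargs):
    ens = _ensemble([state], **kwargs)
    model = generate_structure(ens, ens.structures[0])
    offset = ens.structures[0].numbering_offset
    mapping = ChainMapping(
        pdb_id=model.pdb_id, chain_id="A", accession="P1",
        residue_map={(p + offset, " "): p for p in range(1, len(SEQ) + 1)
                     if model.residue("A", p + offset) is not None},
        canonical_length=len(SEQ),
    )
    return model, mapping


class TestScreenStructure:
    def test_resolution_just_below_cutoff_is_included(self):
        verdict = screen_structure(StructureModel(pdb_id="0001", resolution=2.49))
        assert verdict.included

    def test_resolution_above_cutoff_is_excluded(self):
        verdict = screen_structure(StructureModel(pdb_id="0001", resolution=2.51))
        assert verdict.reasons == ["resolution_gt_2.5"]

    def test_reducing_agent_is_excluded(self):
        model = StructureModel(pdb_id="0001", resolution=1.8, het_codes={"DTT"})
        assert screen_structure(model).reasons == ["reducing_agent"]

    def test_unknown_resolution_is_excluded(self):
        assert screen_structure(StructureModel(pdb_id="0001")).reasons == ["no_resolution"]

    def test_benign_heteroatoms_pass(self):
        model = StructureModel(pdb_id="0001", resolution=1.8, het_codes={"NAG", "ZN"})
        assert screen_structure(model).included


class TestLengthFilter:
    # oracle: arithmetic on the printed 10% rule around 2.038 A
    @pytest.mark.parametrize(
        "d,passes",
        [(2.05, True), (2.30, False), (2.2418, True), (1.8342, True),
         (1.8341, False), (2.2419, False), (2.038, True)],
    )
    def test_ten_percent_window(self, d, passes):
        assert length_filter(_geometry(d=d)) is passes


class TestHarvestBonds:
    def test_single_ssbond_yields_one_mapped_entry(self):
        model, mapping = _model_and_mapping(BondState("present"))
        obs = harvest_bonds(model, {"A": mapping})
        assert len(obs) == 1
        assert (obs[0].accession, obs[0].pos_i, obs[0].pos_j) == ("P1", 15, 35)
        assert obs[0].status == "present"
        assert obs[0].geometry.config is not None

    def test_duplicate_ssbond_lines_collapse(self):
        model, mapping = _model_and_mapping(BondState("present"))
        model.ssbonds.append(model.ssbonds[0])
        assert len(harvest_bonds(model, {"A": mapping})) == 1

    def test_inter_protein_bond_is_logged_not_harvested(self):
        model, mapping = _model_and_mapping(BondState("present"))
        other = ChainMapping(
            pdb_id=model.pdb_id, chain_id="A", accession="P2",
            residue_map=dict(mapping.residue_map), canonical_length=len(SEQ),
        )
        logs: list[str] = []
        # pretend the two endpoints live on chains of different accessions
        model.ssbonds[0].chain2 = "B"
        model.chains["B"] = model.chains["A"]
        obs = harvest_bonds(model, {"A": mapping, "B": other}, logs=logs)
        assert obs == []
        assert any("inter-protein" in line for line in logs)

    def test_dangling_ssbond_is_skipped_with_log(self):
        model, mapping = _model_and_mapping(BondState("present"))
        model.ssbonds.append(SSBondRecord("A", 15, " ", "A", 999, " ", dangling=True))
        logs: list[str] = []
        assert len(harvest_bonds(model, {"A": mapping}, logs=logs)) == 1
        assert any("dangling" in line for line in logs)

    def test_out_of_window_bond_is_filtered_but_kept_as_presence(self):
        model, mapping = _model_and_mapping(BondState("present", spec=CystineSpec(d=2.30)))
        obs = harvest_bonds(model, {"A": mapping})
        assert obs[0].status == "present_filtered_length"


class TestAssessAbsence:
    def test_intact_cysteines_without_ssbond_read_missing(self):
        model, mapping = _model_and_mapping(BondState("reduced"))
        assert assess_absence(model, mapping, (15, 35)) == "missing"

    def test_mutated_cysteine_is_excluded(self):
        model, mapping = _model_and_mapping(BondState("mutated"))
        assert assess_absence(model, mapping, (15, 35)) == "excluded_mutated"

    def test_truncated_construct_is_excluded(self):
        model, mapping = _model_and_mapping(BondState("truncated"))
        assert assess_absence(model, mapping, (15, 35)) == "excluded_truncated"

    def test_missing_sulfur_is_excluded_unresolved(self):
        model, mapping = _model_and_mapping(BondState("unresolved"))
        assert assess_absence(model, mapping, (15, 35)) == "excluded_unresolved"

    def test_interior_gap_is_excluded_unresolved(self):
        model, mapping = _model_and_mapping(BondState("reduced"))
        del mapping.residue_map[(15, " ")]
        assert assess_absence(model, mapping, (15, 35)) == "excluded_unresolved"


def _obs(status, pdb_id="0001", chain="A", resolution=2.0, d=2.04):
    geometry = _geometry(d=d) if status.startswith("present") else None
    return BondObservation(
        accession="P1", pos_i=15, pos_j=35, pdb_id=pdb_id, chain=chain,
        status=status, resolution=resolution, geometry=geometry,
    )


class TestAggregate:
    def test_present_and_valid_missing_makes_labile(self):
        bonds = aggregate([
            _obs("present", "0001"), _obs("present", "0002"), _obs("missing", "0003"),
        ])
        assert len(bonds) == 1 and bonds[0].labile

    def test_absence_only_through_exclusions_is_not_labile(self):
        bonds = aggregate([
            _obs("present", "0001"), _obs("present", "0002"), _obs("excluded_mutated", "0003"),
        ])
        assert not bonds[0].labile

    def test_representative_prefers_best_resolution(self):
        bonds = aggregate([
            _obs("present", "0001", resolution=2.2),
            _obs("present", "0002", resolution=1.4),
            _obs("missing", "0003"),
        ])
        assert bonds[0].representative.pdb_id == "0002"

    def test_representative_tie_breaks_lexicographically(self):
        bonds = aggregate([
            _obs("present", "0002", resolution=1.4),
            _obs("present", "0001", resolution=1.4),
        ])
        assert bonds[0].representative.pdb_id == "0001"

    def test_filtered_presence_counts_for_lability_but_not_geometry(self):
        bonds = aggregate([
            _obs("present_filtered_length", "0001", d=2.4), _obs("missing", "0002"),
        ])
        assert bonds[0].labile
        assert bonds[0].representative.status == "present_filtered_length"

    def test_same_file_lability_flag(self):
        bonds = aggregate([
            _obs("present", "0001", chain="A"), _obs("missing", "0001", chain="B"),
        ])
        assert bonds[0].same_file_lability

    def test_culled_chain_list_restricts_reference_cohort(self):
        observations = [_obs("present", "0001"), _obs("missing", "0002")]
        bonds = aggregate(observations, culled_chains={("0009", "A")})
        assert not bonds[0].in_reference
        bonds = aggregate(observations, culled_chains={("0001", "A")})
        assert bonds[0].in_reference

    def test_monotonicity_of_the_labile_set(self):
        base = [_obs("present", "0001"), _obs("missing", "0002")]
        assert aggregate(base)[0].labile
        # one more valid-missing observation can never retract lability
        assert aggregate(base + [_obs("missing", "0003")])[0].labile
        # excluded observations can never create lability
        stable = [_obs("present", "0001")]
        assert not aggregate(stable + [_obs("excluded_truncated", "0002")])[0].labile

    def test_observations_partition_across_unique_bonds(self, corpus_scan):
        total = sum(len(b.observations) for b in corpus_scan.bonds)
        assert total == len(corpus_scan.observations)
        keys = [(b.accession, b.pos_i, b.pos_j) for b in corpus_scan.bonds]
        assert len(keys) == len(set(keys))
        for bond in corpus_scan.bonds:
            assert all(o.key == (bond.accession, bond.pos_i, bond.pos_j)
                       for o in bond.observations)
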