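"""Residue selection, cluster carving, capping, charges and deck output."""

import numpy as np
import pytest
import biotite.structure as struc

from nkaproton.cluster import (CAP_BOND_LENGTH, CarveError, ClusterModel,
                               QMSettings, carve_cluster, cluster_to_structure,
                               extract_water_shell, select_cluster_residues,
                               write_qm_deck)
from nkaproton.states import ResidueKey, decode_symbol
from nkaproton.synthetic import (make_pocket_structure, make_solvated_ion,
                                 make_toy_chain)


def _add_ion(structure, position, res_id=9000):
    ion = struc.AtomArray(1)
    ion.chain_id[0] = "W"
    ion.res_id[0] = res_id
    ion.res_name[0] = "SOD"
    ion.atom_name[0] = "NA"
    ion.element[0] = "NA"
    ion.coord[0] = position
    return structure + ion


def _ca_of(structure, res_id):
    return structure.coord[(structure.res_id == res_id)
                           & (structure.atom_name == "CA")][0]


@pytest.fixture
def chain_with_ion():
    """Nine-alanine chain with GLU at 5; ion 2.3 Å from the GLU side-chain O."""
    chain = make_toy_chain([(i, "GLU" if i == 5 else "ALA")
                            for i in range(1, 10)])
    o = chain.coord[(chain.res_id == 5) & (chain.atom_name == "OE1")][0]
    return _add_ion(chain, o + np.array([0.0, -2.3, 0.0]))


class TestResidueSelection:
    def test_oxygen_inside_radius_selects_residue(self, chain_with_ion):
        keys = select_cluster_residues(chain_with_ion, hydration_radius=2.5)
        assert ResidueKey("A", 5, "GLU") in keys

    def test_adjacent_residues_ride_along(self, chain_with_ion):
        keys = select_cluster_residues(chain_with_ion, hydration_radius=2.5)
        nums = {k.residue_number for k in keys}
        assert nums == {4, 5, 6}

    def test_far_non_adjacent_residue_excluded(self, chain_with_ion):
        keys = select_cluster_residues(chain_with_ion, hydration_radius=2.5)
        assert all(k.residue_number not in (1, 2, 8, 9) for k in keys)

    def test_order_is_deterministic(self, chain_with_ion):
        keys = select_cluster_residues(chain_with_ion, 2.5)
        assert keys == sorted(keys, key=lambda k: (k.chain_id,
                                                   k.residue_number))

    def test_pocket_structure_selects_all_registry_residues(self, registry):
        pocket = make_pocket_structure(registry, seed=3)
        keys = select_cluster_residues(pocket, 2.5)
        nums = {k.residue_number for k in keys}
        for residue in registry.residues:
            assert residue.residue_number in nums  # plus their neighbours


class TestCarving:
    def _carve(self, structure, nums, symbol, registry, **kw):
        residues = [ResidueKey("A", n, "GLU" if n == 5 else "ALA")
                    for n in nums]
        return carve_cluster(structure, residues,
                             decode_symbol(symbol, registry), **kw)

    def test_interior_fragment_gets_two_caps(self, chain_with_ion, registry):
        model = self._carve(chain_with_ion, (4, 5, 6), "0[000]", registry)
        assert model.cap_count == 2

    def test_terminal_fragment_gets_one_cap(self, chain_with_ion, registry):
        model = self._carve(chain_with_ion, (1, 2), "0[000]", registry)
        assert model.cap_count == 1

    def test_two_fragments_get_four_caps(self, chain_with_ion, registry):
        model = self._carve(chain_with_ion, (2, 3, 7, 8), "0[000]", registry)
        assert model.cap_count == 4

    def test_cap_geometry_along_severed_bond(self, chain_with_ion, registry):
        model = self._carve(chain_with_ion, (4, 5, 6), "0[000]", registry)
        caps = [np.array(a.coord) for a in model.atoms if a.source == "cap"]
        n4 = chain_with_ion.coord[(chain_with_ion.res_id == 4)
                                  & (chain_with_ion.atom_name == "N")][0]
        c3 = chain_with_ion.coord[(chain_with_ion.res_id == 3)
                                  & (chain_with_ion.atom_name == "C")][0]
        d = np.linalg.norm(caps[0] - n4)
        assert d == pytest.approx(CAP_BOND_LENGTH, abs=1e-6)
        cos = (caps[0] - n4) @ (c3 - n4) / (d * np.linalg.norm(c3 - n4))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_alpha_carbons_frozen_one_per_residue(self, chain_with_ion,
                                                  registry):
        model = self._carve(chain_with_ion, (4, 5, 6), "0[000]", registry)
        assert len(model.frozen_atom_ids) == 3
        for i in model.frozen_atom_ids:
            assert model.atoms[i].label.endswith(":CA")

    def test_missing_residue_raises_named_error(self, chain_with_ion,
                                                registry):
        with pytest.raises(CarveError, match="ALA77"):
            carve_cluster(chain_with_ion, [ResidueKey("A", 77, "ALA")],
                          decode_symbol("0[000]", registry))

    def test_net_charge_arithmetic(self, registry):
        """+1 per ion, -1 per deprotonated Glu/Asp included."""
        pocket = make_pocket_structure(registry, seed=0)
        residues = select_cluster_residues(pocket, 2.5)
        all_deprot = carve_cluster(pocket, residues,
                                   decode_symbol("0[000]", registry))
        assert all_deprot.net_charge == 3 - 6
        three = carve_cluster(pocket, residues,
                              decode_symbol("3[EEE]", registry))
        assert three.net_charge == 3 - 3
        full = carve_cluster(pocket, residues,
                             decode_symbol("6[222]", registry))
        assert full.net_charge == 3

    def test_charge_steps_with_each_proton(self, registry):
        pocket = make_pocket_structure(registry, seed=0)
        residues = select_cluster_residues(pocket, 2.5)
        charges = [carve_cluster(pocket, residues,
                                 decode_symbol(sym, registry)).net_charge
                   for sym in ("0[000]", "1[E00]", "2[200]", "3[2E0]")]
        assert charges == [-3, -2, -1, 0]

    def test_carving_is_idempotent(self, registry):
        pocket = make_pocket_structure(registry, seed=1)
        residues = select_cluster_residues(pocket, 2.5)
        state = decode_symbol("3[EEE]", registry)
        model = carve_cluster(pocket, residues, state)
        again = carve_cluster(cluster_to_structure(model), residues, state)
        assert again.n_atoms == model.n_atoms  # nothing added
        assert again.cap_count == 0  # old caps ride along; no bond re-severed
        assert again.net_charge == model.net_charge

    def test_waters_included_within_cutoff_only(self, registry):
        pocket = make_pocket_structure(registry, n_near_waters=4,
                                       n_far_waters=3, seed=2)
        residues = select_cluster_residues(pocket, 2.5)
        model = carve_cluster(pocket, residues,
                              decode_symbol("0[000]", registry),
                              water_cutoff=5.0)
        water_atoms = [a for a in model.atoms if a.source == "water"]
        assert len(water_atoms) == 4 * 3  # whole molecules, O+2H each


class TestWaterShell:
    def test_inside_outside_partition(self):
        ion = _add_ion(struc.AtomArray(0), (0.0, 0.0, 0.0))
        records = []
        for k, r in enumerate((3.0, 5.0, 8.0, 10.0, 12.0)):
            w = struc.AtomArray(1)
            w.chain_id[0] = "W"
            w.res_id[0] = k + 1
            w.res_name[0] = "HOH"
            w.atom_name[0] = "OH2"
            w.element[0] = "O"
            w.coord[0] = (r, 0, 0)
            records.append(w)
        solvated = ion
        for w in records:
            solvated = solvated + w
        shell = extract_water_shell(solvated, radius=9.0)
        assert shell.n_waters == 3

    def test_tiny_radius_gives_empty_shell(self):
        solvated = make_solvated_ion(seed=4)
        assert extract_water_shell(solvated, radius=0.1).n_waters == 0

    def test_bulk_density_gives_order_100_waters(self):
        solvated = make_solvated_ion(radius=12.0, seed=7)
        shell = extract_water_shell(solvated, radius=9.0)
        assert 60 <= shell.n_waters <= 170


class TestDeckEmission:
    def test_xyz_counts_match_model_including_caps(self, chain_with_ion,
                                                   registry):
        residues = [ResidueKey("A", n, "GLU" if n == 5 else "ALA")
                    for n in (4, 5, 6)]
        model = carve_cluster(chain_with_ion, residues,
                              decode_symbol("0[000]", registry))
        deck, xyz = write_qm_deck(model)
        lines = xyz.strip().splitlines()
        assert int(lines[0]) == model.n_atoms
        assert len(lines) - 2 == model.n_atoms
        assert f"natoms {model.n_atoms}" in deck

    def test_frozen_indices_listed_one_based(self):
        from nkaproton.cluster import ClusterAtom
        model = ClusterModel(
            atoms=[ClusterAtom("C", (0.0, 0.0, 0.0), "residue"),
                   ClusterAtom("O", (1.0, 0.0, 0.0), "residue"),
                   ClusterAtom("C", (2.0, 0.0, 0.0), "residue")],
            residues=[], frozen_atom_ids=[0, 2], net_charge=0)
        deck, _ = write_qm_deck(model)
        assert "frozen 1 3" in deck

    def test_byte_stable_output(self, registry):
        pocket = make_pocket_structure(registry, seed=5)
        residues = select_cluster_residues(pocket, 2.5)
        model = carve_cluster(pocket, residues,
                              decode_symbol("3[EEE]", registry))
        assert write_qm_deck(model) == write_qm_deck(model)

    def test_unset_charge_rejected(self):
        class Bare:
            atoms = [1]
            frozen_atom_ids = []
        with pytest.raises(CarveError):
            write_qm_deck(Bare())

    def test_settings_keywords_appear(self, registry):
        pocket = make_pocket_structure(registry, seed=5)
        residues = select_cluster_residues(pocket, 2.5)
        model = carve_cluster(pocket, residues,
                              decode_symbol("3[EEE]", registry))
        deck, _ = write_qm_deck(model, QMSettings(extra_keywords=("opt",)))
        assert "! B3LYP 6-31G** GD3" in deck and "! opt" in deck
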