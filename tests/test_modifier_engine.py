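from collections import Counter

import numpy as np
import pytest

from ptmgraft import (
    ModificationOptions,
    PeptideSpec,
    apply_ptm,
    build_peptide,
    compute_sasa,
    find_candidates,
    get_definition,
    modify,
)
from ptmgraft.modifier_engine import OUTCOMES
from ptmgraft.structure_io import Structure

from conftest import merge_structures, translate


def test_nitration_skips_existing_niy():
    s = build_peptide(PeptideSpec("YAYAY"))
    # pre-modify the middle tyrosine
    modify(s, ModificationOptions(ptm_class="nitration", selection="resi 3"))
    opts = ModificationOptions(ptm_class="nitration")
    cands = find_candidates(s, opts)
    assert len(cands) == 2
    assert {c.residue.resi for c in cands} == {1, 5}


def test_proline_n_terminus_not_a_candidate():
    s = build_peptide(PeptideSpec("PAK"))
    opts = ModificationOptions(ptm_class="acetylation", include_n_termini=True)
    cands = find_candidates(s, opts)
    assert all(c.site == "sidechain" for c in cands)
    assert {c.residue.resn for c in cands} == {"LYS"}


def test_nonproline_n_terminus_is_candidate():
    s = build_peptide(PeptideSpec("GAK"))
    opts = ModificationOptions(ptm_class="acetylation", include_n_termini=True)
    cands = find_candidates(s, opts)
    sites = {(c.residue.resi, c.site) for c in cands}
    assert (1, "nterm") in sites and (3, "sidechain") in sites


def test_surface_cutoff_filters_buried_lysine(buried_exposed_lys):
    structure, buried, exposed = buried_exposed_lys
    sasa = compute_sasa(structure)
    opts = ModificationOptions(ptm_class="mda_adduct", surface_cutoff=25.0)
    cands = find_candidates(structure, opts, sasa)
    assert [c.residue.chain_id for c in cands] == ["B"]


def test_surface_cutoff_requires_sasa(buried_exposed_lys):
    structure, _, _ = buried_exposed_lys
    with pytest.raises(ValueError):
        find_candidates(structure, ModificationOptions(ptm_class="mda_adduct", surface_cutoff=25.0))


def test_buried_residue_reported_as_skipped(buried_exposed_lys):
    structure, _, _ = buried_exposed_lys
    report = modify(structure, ModificationOptions(ptm_class="mda_adduct", surface_cutoff=25.0))
    assert report.n_modified == 1
    assert report.count("skipped_buried") == 1
    assert report.n_candidates == 2


def test_tyr_to_niy_gains_three_heavy_atoms():
    s = build_peptide(PeptideSpec("AYA"))
    tyr = s.residues[1]
    before = len(tyr.heavy_atoms())
    defn = get_definition("nitration")
    entry = apply_ptm(s, tyr, defn, ModificationOptions(ptm_class="nitration"))
    assert entry.outcome == "modified"
    assert tyr.resn == "NIY"
    assert len(tyr.heavy_atoms()) == before + 3


def test_arg_to_cir_conserves_heavy_atoms():
    s = build_peptide(PeptideSpec("ARA"))
    arg = s.residues[1]
    before = len(arg.heavy_atoms())
    entry = apply_ptm(
        s, arg, get_definition("citrullination"), ModificationOptions(ptm_class="citrullination")
    )
    assert entry.outcome == "modified"
    assert arg.resn == "CIR"
    assert len(arg.heavy_atoms()) == before
    assert arg.atom("NH1") is None and arg.atom("O7").element == "O"


def test_double_application_skipped_and_unchanged():
    s = build_peptide(PeptideSpec("AYA"))
    tyr = s.residues[1]
    opts = ModificationOptions(ptm_class="nitration")
    defn = get_definition("nitration")
    assert apply_ptm(s, tyr, defn, opts).outcome == "modified"
    coords = {a.name: a.coords.copy() for a in tyr.atoms}
    entry = apply_ptm(s, tyr, defn, opts)
    assert entry.outcome == "skipped_already_modified"
    assert {a.name: tuple(a.coords) for a in tyr.atoms} == {
        n: tuple(c) for n, c in coords.items()
    }


def test_modify_idempotent():
    s = build_peptide(PeptideSpec("KAKAK"))
    opts = ModificationOptions(ptm_class="mda_adduct")
    first = modify(s, opts)
    assert first.n_modified == 3
    second = modify(s, opts)
    assert second.n_modified == 0


def test_missing_target_atom_skipped_not_crash():
    s = build_peptide(PeptideSpec("AKA"))
    lys = s.residues[1]
    s.remove_atom(lys.atom("NZ"))
    entry = apply_ptm(
        s, lys, get_definition("acetylation"), ModificationOptions(ptm_class="acetylation")
    )
    assert entry.outcome == "skipped_missing_atoms"
    assert "NZ" in entry.detail


def test_disulfide_cysteines_excluded():
    a = build_peptide(PeptideSpec("AC", chain_id="A"))
    b = build_peptide(PeptideSpec("CA", chain_id="B"))
    sg_a = a.residues[1].atom("SG")
    sg_b = b.residues[0].atom("SG")
    translate(b, sg_a.coords + np.array([2.0, 0.0, 0.0]) - sg_b.coords)
    s = merge_structures(a, b)
    cands = find_candidates(s, ModificationOptions(ptm_class="cysteine_oxidation"))
    assert cands == []


def test_tripeptide_maa_charge_ledger():
    s = build_peptide(PeptideSpec("KAK"))
    report = modify(s, ModificationOptions(ptm_class="mda_adduct"))
    assert report.n_modified == 2
    assert report.total_charge_delta == -2


def test_zero_target_structure():
    s = build_peptide(PeptideSpec("AGA"))
    report = modify(s, ModificationOptions(ptm_class="phosphorylation"))
    assert report.n_candidates == 0
    assert report.n_modified == 0


def test_report_counts_partition_candidates(buried_exposed_lys):
    structure, _, _ = buried_exposed_lys
    report = modify(
        structure, ModificationOptions(ptm_class="mda_adduct", surface_cutoff=25.0)
    )
    outcome_counts = Counter(e.outcome for e in report.entries)
    assert set(outcome_counts) <= set(OUTCOMES)
    assert sum(outcome_counts.values()) == report.n_candidates
    totals = report.totals()
    assert totals["modified"] + sum(totals[o] for o in OUTCOMES[1:]) == totals["candidates"]


def test_unmodified_residues_bitwise_unchanged():
    s = build_peptide(PeptideSpec("KAYAK"))
    before = {
        a.key: a.coords.copy()
        for r in s.residues
        if r.resn != "LYS"
        for a in r.atoms
    }
    modify(s, ModificationOptions(ptm_class="mda_adduct", optimization_level=2))
    for r in s.residues:
        for a in r.atoms:
            if a.key in before:
                assert np.array_equal(a.coords, before[a.key])


def test_chain_order_does_not_change_outcome_counts():
    a1 = build_peptide(PeptideSpec("KAK", chain_id="A"))
    b1 = translate(build_peptide(PeptideSpec("AKY", chain_id="B")), [40.0, 0, 0])
    s_ab = merge_structures(a1, b1)

    a2 = build_peptide(PeptideSpec("KAK", chain_id="A"))
    b2 = translate(build_peptide(PeptideSpec("AKY", chain_id="B")), [40.0, 0, 0])
    s_ba = merge_structures(b2, a2)

    opts = ModificationOptions(ptm_class="methylation")
    rep1 = modify(s_ab, opts)
    rep2 = modify(s_ba, opts)
    multiset = lambda rep: Counter((e.chain_id, e.resi, e.outcome) for e in rep.entries)
    assert multiset(rep1) == multiset(rep2)


def test_product_resn_or_tag_set_for_every_modified_residue():
    s = build_peptide(PeptideSpec("GKS"))
    opts = ModificationOptions(ptm_class="methylation", include_n_termini=True)
    report = modify(s, opts)
    for e in report.entries:
        if e.outcome != "modified":
            continue
        res = s.residue(e.chain_id, e.resi, e.icode)
        if e.site == "sidechain":
            assert res.resn == e.product_resn == "MLZ"
        else:
            assert res.resn == e.original_resn  # N-terminal caps keep the name
            assert "@nterm" in (res.ptm_tag or "")


def test_nterm_acetylation_on_tyrosine_avoids_name_collision():
    s = build_peptide(PeptideSpec("YAA"))
    opts = ModificationOptions(ptm_class="acetylation", include_n_termini=True)
    report = modify(s, opts)
    assert report.n_modified == 1
    tyr = s.residues[0]
    assert tyr.resn == "TYR"
    assert tyr.atom("CNT") is not None and tyr.atom("ONT") is not None
    assert tyr.atom("OH") is not None  # ring hydroxyl untouched


def test_racemic_choice_picks_a_concrete_isomer():
    s = build_peptide(PeptideSpec("AMA"))
    report = modify(s, ModificationOptions(ptm_class="methionine_oxidation"))
    (entry,) = [e for e in report.entries if e.outcome == "modified"]
    assert entry.variant in ("R", "S")
    assert s.residues[1].resn == "SME"


def test_nitration_position_override():
    for pos, carbon in ((1, "CE1"), (2, "CE2")):
        s = build_peptide(PeptideSpec("AYA"))
        report = modify(
            s, ModificationOptions(ptm_class="nitration", position_override=pos)
        )
        (entry,) = report.entries
        assert entry.position == pos
        tyr = s.residues[1]
        nn = tyr.atom("NN")
        assert np.linalg.norm(nn.coords - tyr.atom(carbon).coords) < 1.6


def test_remark_provenance_recorded():
    s = build_peptide(PeptideSpec("AYA"))
    modify(s, ModificationOptions(ptm_class="nitration"))
    assert any("PTMGRAFT nitration" in r for r in s.remarks)


def test_strain_after_le_before_when_optimized():
    s = build_peptide(PeptideSpec("KYKYK"))
    report = modify(s, ModificationOptions(ptm_class="mda_adduct", optimization_level=1))
    for e in report.entries:
        if e.outcome == "modified":
            assert e.strain_after <= e.strain_before + 1e-12
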