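import math

import numpy as np
import pytest

from bcmine import (
    DegenerateFragmentError,
    Fragment,
    GeneratorSpec,
    LoopQuery,
    SearchParams,
    clash_check,
    detect_gaps,
    frag_search,
    graft_loop,
    ideal_helix,
    loop_search,
    make_loop_query,
    mirror,
    mirror_search,
    random_walk_fragment,
    read_structure,
    specificity_search,
    synthetic_bank,
)
from bcmine.synth import write_pdb
from naive_oracles import (
    naive_frag_search,
    naive_loop_search,
    naive_specificity,
)

RELAXED = SearchParams(bc_cutoff=0.5, rigidity_cutoff=3.0)


# -- frag search ------------------------------------------------------------


def test_planted_identity_window_is_recovered(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    hits = frag_search(query, bank)
    assert hits, "planted window not found"
    top = hits[0]
    assert top.hit_id == truth["planted"]["structure_id"]
    assert top.h_start == f"A:{truth['planted']['start_label']}"
    assert top.bc == 1.0
    assert top.rigidity == 0.0
    assert top.rmsd == pytest.approx(0.0, abs=1e-9)
    assert top.is_self  # the query carries the planted window's provenance


def test_planted_window_found_at_any_cutoff(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    for bc_cut, rig_cut in [(1.0, 0.0), (0.95, 1.0), (0.5, 10.0)]:
        hits = frag_search(query, bank, SearchParams(bc_cutoff=bc_cut,
                                                     rigidity_cutoff=rig_cut))
        assert any(h.hit_id == truth["planted"]["structure_id"]
                   and h.h_start.endswith(truth["planted"]["start_label"])
                   for h in hits)


@pytest.mark.parametrize("params", [SearchParams(), RELAXED,
                                    SearchParams(bc_cutoff=0.8, rigidity_cutoff=0.5)],
                         ids=["default", "relaxed", "tight-rigidity"])
def test_frag_search_matches_naive_oracle(walk_bank, params):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    got = frag_search(query, bank, params)
    want = naive_frag_search(query, bank, params)
    assert [(h.hit_id, h.h_start) for h in got] == \
        [(r["hit_id"], r["h_start"]) for r in want]
    for h, r in zip(got, want):
        assert h.bc == pytest.approx(r["bc"], abs=1e-10)
        assert h.rigidity == pytest.approx(r["rigidity"], abs=1e-10)


def test_no_filtering_returns_every_nondegenerate_window(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    hits = frag_search(query, bank, SearchParams(bc_cutoff=1e-12,
                                                 rigidity_cutoff=1e12))
    want = naive_frag_search(query, bank,
                             SearchParams(bc_cutoff=1e-12, rigidity_cutoff=1e12))
    # only positive-BC windows pass the floor cutoff; mirror side symmetric
    assert len(hits) == len(want)


def test_threshold_monotonicity(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    base = {(h.hit_id, h.h_start)
            for h in frag_search(query, bank, SearchParams(0.5, 2.0))}
    for bc_cut, rig_cut in [(0.6, 2.0), (0.5, 1.0), (0.9, 0.5)]:
        tighter = {(h.hit_id, h.h_start)
                   for h in frag_search(query, bank, SearchParams(bc_cut, rig_cut))}
        assert tighter <= base


def test_degenerate_query_is_an_error(walk_bank):
    bank, _ = walk_bank
    line = np.column_stack([np.arange(9.0) * 3.8, np.zeros(9), np.zeros(9)])
    with pytest.raises(DegenerateFragmentError):
        frag_search(Fragment(coords=line), bank)


def test_oversized_window_gives_empty_result_not_error(walk_bank):
    bank, _ = walk_bank
    assert frag_search(random_walk_fragment(80, seed=9), bank) == []


def test_hit_order_is_total_and_deterministic(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    a = frag_search(query, bank, RELAXED)
    b = frag_search(query, bank, RELAXED)
    assert [(h.hit_id, h.h_start, h.bc, h.rigidity) for h in a] == \
        [(h.hit_id, h.h_start, h.bc, h.rigidity) for h in b]
    keys = [(-h.bc, h.rigidity, h.hit_id, h.h_key) for h in a]
    assert keys == sorted(keys)


# -- mirror search ----------------------------------------------------------


def test_planted_mirror_window_is_recovered(tmp_path):
    specs = [GeneratorSpec("random_walk", length=30, seed=200 + i) for i in range(6)]
    bank, truth = synthetic_bank(specs, tmp_path / "mb",
                                 planted=(mirror(ideal_helix(9)), 2, 8))
    # query = mirror image of the bank window, exactly as stored on disk
    query = mirror(truth["planted"]["fragment"])
    hits = mirror_search(query, bank)
    assert hits
    top = hits[0]
    assert top.hit_id == "synth_002" and top.h_start == "A:9"
    assert top.bc == -1.0
    assert top.rigidity == 0.0
    # RMSD is reported against the mirrored query
    assert top.rmsd == pytest.approx(0.0, abs=1e-9)


def test_mirror_equals_frag_search_of_mirrored_query(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    m = mirror_search(query, bank, RELAXED)
    f = frag_search(mirror(query), bank, RELAXED)
    assert {(h.hit_id, h.h_start) for h in m} == {(h.hit_id, h.h_start) for h in f}
    for hm, hf in zip(sorted(m, key=lambda h: (h.hit_id, h.h_start)),
                      sorted(f, key=lambda h: (h.hit_id, h.h_start))):
        assert hm.bc == pytest.approx(-hf.bc, abs=1e-9)


def test_mirror_search_matches_naive_oracle(walk_bank):
    bank, truth = walk_bank
    query = truth["planted"]["fragment"]
    for params in (SearchParams(), RELAXED):
        got = mirror_search(query, bank, params)
        want = naive_frag_search(query, bank, params, mirrored=True)
        assert [(h.hit_id, h.h_start) for h in got] == \
            [(r["hit_id"], r["h_start"]) for r in want]
        keys = [(h.bc, h.rigidity, h.hit_id, h.h_key) for h in got]
        assert keys == sorted(keys)  # ascending BC for the mirror service


# -- loop search ------------------------------------------------------------


@pytest.fixture
def loop_setup(tmp_path):
    """A template with its own loop excised; the intact template in the bank."""
    full = random_walk_fragment(30, seed=77, sequence="ACDEFGHIKLMNPQRSTVWYACDEFGHIKL")
    missing = range(12, 17)  # 5-residue loop
    keep = [i for i in range(30) if i not in missing]
    gapped = tmp_path / "gapped.pdb"
    write_pdb(gapped, [("A", [i + 1 for i in keep],
                        "".join(full.sequence[i] for i in keep), full.coords[keep])])
    specs = [GeneratorSpec("random_walk", length=30, seed=300 + i) for i in range(5)]
    bank, truth = synthetic_bank(specs, tmp_path / "lb")
    # plant the intact template as one more bank structure
    intact = tmp_path / "lb" / "intact.pdb"
    write_pdb(intact, [("A", 1, full.sequence, full.coords)])
    from bcmine import build_bank
    bank = build_bank(truth["files"] + [str(intact)])
    st = read_structure(gapped)
    gaps = detect_gaps(full.sequence, st)
    assert len(gaps) == 1 and gaps[0].searchable
    lq = make_loop_query(st, full.sequence, gaps[0])
    native_loop = np.round(full.coords[list(missing)], 3)
    return lq, bank, native_loop


def test_native_loop_recovery(loop_setup):
    lq, bank, native_loop = loop_setup
    hits = loop_search(lq, bank)
    native = [h for h in hits if h.hit_id == "intact"]
    assert native, "native window not recovered"
    top = native[0]
    assert top.bc == pytest.approx(1.0, abs=1e-9)
    assert top.rigidity == pytest.approx(0.0, abs=1e-9)
    assert top.rmsd == pytest.approx(0.0, abs=1e-9)
    # grafted loop reproduces the excised native loop
    assert np.allclose(top.loop_coords, native_loop, atol=1e-6)


def test_loop_search_matches_naive_oracle(loop_setup):
    lq, bank, _ = loop_setup
    for params in (SearchParams(), SearchParams(bc_cutoff=0.5, rigidity_cutoff=3.0)):
        got = loop_search(lq, bank, params)
        want = naive_loop_search(lq, bank, params)
        assert [(h.hit_id, h.h_start) for h in got] == \
            [(r["hit_id"], r["h_start"]) for r in want]
        for h, r in zip(got, want):
            assert h.bc == pytest.approx(r["bc"], abs=1e-9)


def test_graft_is_rigid_and_consistent(loop_setup):
    lq, bank, _ = loop_setup
    hits = loop_search(lq, bank, SearchParams(bc_cutoff=0.5, rigidity_cutoff=3.0))
    for h in hits[:5]:
        seg = next(s for s in bank.segments if s.structure_id == h.hit_id)
        start = next(i for i in range(len(seg))
                     if f"{seg.chain_id}:{seg.residues[i].label}" == h.h_start)
        window = seg.fragment(start, 8 + lq.gap_length)
        loop = graft_loop(window, lq)
        # rigid: intra-loop distances preserved
        orig = window.coords[4:4 + lq.gap_length]
        d0 = np.linalg.norm(orig[:, None] - orig[None, :], axis=2)
        d1 = np.linalg.norm(loop[:, None] - loop[None, :], axis=2)
        assert np.allclose(d0, d1, atol=1e-9)
        assert np.allclose(loop, h.loop_coords, atol=1e-9)


# -- clash checking ---------------------------------------------------------


def _toy_loop_query(template):
    helix = ideal_helix(13)
    return LoopQuery(
        n_flank=Fragment(coords=helix.coords[:4]),
        c_flank=Fragment(coords=helix.coords[9:13]),
        gap_length=5,
        template_coords=template,
        loop_seq_indices=[10, 11, 12, 13, 14],
    )


def test_clash_far_template_passes():
    template = [("A", 30, (100.0, 100.0, 100.0))]
    lq = _toy_loop_query(template)
    assert clash_check(np.zeros((5, 3)), lq)


def test_clash_at_29_angstrom_distant_residue_fails():
    # template residue 10 positions away, 2.9 Å from a loop atom
    template = [("A", 0, (2.9, 0.0, 0.0))]
    lq = _toy_loop_query(template)
    loop = np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]])
    assert not clash_check(loop, lq)


def test_clash_exempts_sequence_neighbours():
    # same 2.9 Å contact but separation 1 (< min_seq_sep 3): exempt
    template = [("A", 9, (2.9, 0.0, 0.0))]
    lq = _toy_loop_query(template)
    loop = np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]])
    assert clash_check(loop, lq)


def test_clash_other_chain_always_checked():
    template = [("B", None, (2.9, 0.0, 0.0))]
    lq = _toy_loop_query(template)
    loop = np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0], [40, 0, 0]])
    assert not clash_check(loop, lq)


def test_clashing_candidate_is_discarded(loop_setup):
    lq, bank, _ = loop_setup
    # poison the template with an obstacle right on the native loop path,
    # far in sequence: the native candidate must now be rejected
    hits = loop_search(lq, bank)
    native = next(h for h in hits if h.hit_id == "intact")
    obstacle = tuple(native.loop_coords[2])
    lq.template_coords.append(("A", 0, obstacle))
    hits2 = loop_search(lq, bank)
    assert all(h.hit_id != "intact" or h.h_start != native.h_start for h in hits2)


# -- specificity ------------------------------------------------------------


def test_sp_formula_engineered_counts(tmp_path):
    query = ideal_helix(9)
    qpath = tmp_path / "q.pdb"
    write_pdb(qpath, [("A", 1, query.sequence, query.coords)])
    qst = read_structure(qpath)

    # planted in 1 of 4 -> sp = 0.75
    specs = [GeneratorSpec("random_walk", length=25, seed=400 + i) for i in range(4)]
    bank, _ = synthetic_bank(specs, tmp_path / "b1", planted=(query, 1, 6))
    prof = specificity_search(qst, bank)
    assert prof.n_total == 4
    assert [w.sp for w in prof.windows] == [pytest.approx(0.75)]

    # in none of 4 -> sp = 1
    bank0, _ = synthetic_bank(specs, tmp_path / "b0")
    prof0 = specificity_search(qst, bank0)
    assert [w.sp for w in prof0.windows] == [pytest.approx(1.0)]

    # in all 4 -> sp = 0
    specs_all = [GeneratorSpec("random_walk", length=25, seed=400 + i) for i in range(4)]
    banks = []
    for i in range(4):
        b, _ = synthetic_bank(specs_all, tmp_path / f"ba{i}", planted=(query, i, 6))
        banks.append(b)
    from bcmine import FragmentBank
    merged = FragmentBank(
        segments=[s for i, b in enumerate(banks) for s in b.segments
                  if s.structure_id == f"synth_{i:03d}"])
    prof_all = specificity_search(qst, merged)
    assert prof_all.n_total == 4
    assert [w.sp for w in prof_all.windows] == [pytest.approx(0.0)]


def test_sp_decreases_when_matching_protein_added(tmp_path):
    query = ideal_helix(9)
    qpath = tmp_path / "q.pdb"
    write_pdb(qpath, [("A", 1, query.sequence, query.coords)])
    qst = read_structure(qpath)
    specs = [GeneratorSpec("random_walk", length=25, seed=410 + i) for i in range(3)]
    bank, _ = synthetic_bank(specs, tmp_path / "grow", planted=(query, 0, 5))
    sp3 = specificity_search(qst, bank).windows[0].sp
    specs4 = specs + [GeneratorSpec("random_walk", length=25, seed=450)]
    bank4, _ = synthetic_bank(specs4, tmp_path / "grow4", planted=(query, 3, 5))
    # same three decoys plus one more protein containing the query window
    from bcmine import FragmentBank
    merged = FragmentBank(segments=bank.segments
                          + [s for s in bank4.segments if s.structure_id == "synth_003"])
    sp4 = specificity_search(qst, merged).windows[0].sp
    assert sp4 < sp3


def test_specificity_matches_naive_oracle(tmp_path):
    specs = [GeneratorSpec("random_walk", length=20, seed=420 + i) for i in range(4)]
    bank, truth = synthetic_bank(specs, tmp_path / "sb",
                                 planted=(ideal_helix(9), 0, 4))
    qst = read_structure(truth["files"][0])
    params = SearchParams(bc_cutoff=0.8, rigidity_cutoff=2.0)
    prof = specificity_search(qst, bank, params)
    from bcmine import contiguous_segments
    want = naive_specificity(contiguous_segments(qst), bank, params)
    got = [(w.chain_id, w.start, w.sp) for w in prof.windows]
    assert len(got) == len(want)
    for (gc, gs, gsp), (wc, ws, wsp) in zip(got, want):
        assert (gc, gs) == (wc, ws)
        assert gsp == pytest.approx(wsp, abs=1e-12) or (math.isnan(gsp) and math.isnan(wsp))


def test_specificity_residue_score_is_max_over_windows(tmp_path):
    specs = [GeneratorSpec("random_walk", length=20, seed=430 + i) for i in range(3)]
    bank, truth = synthetic_bank(specs, tmp_path / "rb")
    qst = read_structure(truth["files"][0])
    prof = specificity_search(qst, bank, SearchParams(bc_cutoff=0.8, rigidity_cutoff=2.0))
    by_res = {(c, lbl): sp for c, lbl, sp in prof.residues}
    for w in prof.windows:
        if math.isnan(w.sp):
            continue
        for num in range(int(w.start), int(w.end) + 1):
            assert by_res[("A", str(num))] >= w.sp - 1e-12
    assert all(0.0 <= sp <= 1.0 for sp in by_res.values())


def test_specificity_classification_filters(tmp_path):
    query = ideal_helix(9)
    qpath = tmp_path / "q.pdb"
    write_pdb(qpath, [("A", 1, query.sequence, query.coords)])
    qst = read_structure(qpath)
    specs = [GeneratorSpec("random_walk", length=25, seed=440 + i) for i in range(4)]
    manifest = {0: "b.1.1.1", 1: "b.47.1.1", 2: "b.47.2.1", 3: "g.3.1.1"}
    bank, _ = synthetic_bank(specs, tmp_path / "fb", planted=(query, 1, 6),
                             manifest=manifest)
    prof = specificity_search(qst, bank, include_sccs="b", exclude_sccs="b.47")
    assert prof.n_total == 1  # only the b.1 structure remains
    assert [w.sp for w in prof.windows] == [pytest.approx(1.0)]
    from bcmine import EmptyBankError
    with pytest.raises(EmptyBankError):
        specificity_search(qst, bank, include_sccs="c")
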