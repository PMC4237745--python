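"""The learning protocol: tag libraries, annealing, extension, digestion,
separation, by-products, classification, screening."""

import numpy as np
import pytest

from biomemory import learning, thermo
from biomemory.genome import Fragment, FragmentPool
from biomemory.learning import (
    DEFAULT_TAG_SEQ,
    AnnealingEvent,
    LearnedProduct,
    bead_separate,
    classify_products,
    klenow_extend,
    make_tag_library,
    nch_screen,
    run_learning,
    tag_tag_byproducts,
)
from biomemory.seqs import revcomp
from conftest import make_tags_from_probes

COND = thermo.LEARNING_CONDITIONS


def frag(seq, pid="f", strand="+", start=0):
    return Fragment(pid, strand, start, start + len(seq), seq)


# ------------------------------------------------------------- tag library


def test_tag_library_determinism_and_shape():
    a = make_tag_library(50, seed=1)
    b = make_tag_library(50, seed=1)
    assert np.array_equal(a.probes, b.probes)
    tag = a[0]
    assert tag.tag_seq == DEFAULT_TAG_SEQ
    assert len(tag.full_sequence) == 40
    assert a.design_space == 4**20


def test_tag_library_probe_base_frequencies():
    """Probe bases are uniform: each frequency within 3 s.d. of 0.25."""
    lib = make_tag_library(10_000, seed=2)
    n = lib.probes.size
    sd = (n * 0.25 * 0.75) ** 0.5
    for base in range(4):
        assert abs(int((lib.probes == base).sum()) - 0.25 * n) < 3 * sd


def test_tag_library_validation():
    with pytest.raises(ValueError):
        make_tag_library(0, seed=1)
    with pytest.raises(ValueError):
        make_tag_library(1, seed=1, tag_seq="ACGT")
    with pytest.raises(ValueError):
        learning.MemoryTag(DEFAULT_TAG_SEQ, "A" * 19)


# ------------------------------------------------------------- annealing


def test_anneal_finds_planted_full_probe_site():
    """A template containing a probe's exact complement yields d=20, p=20."""
    lib = make_tag_library(1, seed=3)
    probe = lib.probe_seq(0)
    template = "ACGTAC" + revcomp(probe) + "GGTACG"
    pool = FragmentPool([frag(template)])
    events = learning.anneal(lib, pool, temperature=40.0, seed=0)
    assert len(events) == 1
    ev = events[0]
    assert (ev.d, ev.p, ev.template_pos) == (20, 20, 6)


def test_enumerate_annealing_sites_equals_brute_force_triples():
    """All qualifying (p, d, w) triples equal an exhaustive string scan."""
    rng = np.random.default_rng(8)
    lib = make_tag_library(12, seed=9)
    seqs = ["".join(rng.choice(list("ACGT"), 90)) for _ in range(2)]
    seqs[0] = seqs[0][:30] + revcomp(lib.probe_seq(0)[5:17]) + seqs[0][42:]
    pool = FragmentPool([frag(s, pid=f"f{i}") for i, s in enumerate(seqs)])
    temperature, k_min = 25.0, 5
    got = {
        (e.tag_index, e.template_index, e.p, e.d, e.template_pos)
        for e in learning.enumerate_annealing_sites(
            lib, pool, temperature, COND, k_min, all_windows=True
        )
    }
    brute = set()
    for ti in range(len(lib)):
        probe = lib.probe_seq(ti)
        for fi, s in enumerate(seqs):
            for d in range(k_min, 21):
                for q in range(0, 21 - d):
                    sub = probe[q : q + d]
                    for w in range(0, len(s) - d + 1):
                        if sub == revcomp(s[w : w + d]):
                            if thermo.tm_duplex(s[w : w + d], COND) >= temperature:
                                brute.add((ti, fi, 20 + q, d, w))
    assert got == brute
    assert any(e[0] == 0 and e[3] >= 12 for e in got)  # planted site present


def test_anneal_exclusive_occupancy():
    """Two tags with the same probe cannot occupy one template site twice."""
    probe = "GCATCGGATCTGAGCCTTGC"
    lib = make_tags_from_probes([probe, probe])
    pool = FragmentPool([frag("AT" + revcomp(probe) + "CG")])
    events = learning.anneal(lib, pool, temperature=40.0, seed=1)
    assert len(events) == 1


def test_anneal_requires_k_min():
    lib = make_tag_library(1, seed=0)
    with pytest.raises(ValueError):
        learning.anneal(lib, FragmentPool([]), 25.0, k_min=1)


# ------------------------------------------------------------- extension


def test_klenow_extend_trims_tail_and_copies_template():
    """p=20, d=12 (8-base 3' tail trimmed) on a template with 60 bases 5'
    of the duplex gives a 92-base LP_H product."""
    lib = make_tag_library(1, seed=4)
    probe = lib.probe_seq(0)
    # duplex pairs probe bases 0..11 (p=20, d=12); template: 60 bases, then
    # the 12-base complement window, then more 3' sequence
    rng = np.random.default_rng(5)
    left = "".join(rng.choice(list("ACGT"), 60))
    right = "".join(rng.choice(list("ACGT"), 10))
    template = left + revcomp(probe[0:12]) + right
    ev = AnnealingEvent(0, "fragment", 0, p=20, d=12, template_pos=60, tm=50.0)
    prod = klenow_extend(ev, template, lib[0])
    assert len(prod) == (20 + 12) + 60 == 92
    assert prod.length_class == "LP_H"
    assert prod.sequence == lib.full_sequence(0)[:32] + revcomp(left)


def test_klenow_extend_flush_duplex_gives_tag_only():
    """A full-probe duplex flush with the template 5' end extends by zero."""
    lib = make_tag_library(1, seed=6)
    template = revcomp(lib.probe_seq(0)) + "ACGTACGT"
    ev = AnnealingEvent(0, "fragment", 0, p=20, d=20, template_pos=0, tm=60.0)
    prod = klenow_extend(ev, template, lib[0])
    assert len(prod) == 40 and prod.length_class == "TAG_ONLY"


def test_klenow_extend_rejects_mismatched_event():
    lib = make_tag_library(1, seed=7)
    ev = AnnealingEvent(0, "fragment", 0, p=20, d=10, template_pos=5, tm=50.0)
    with pytest.raises(ValueError):
        klenow_extend(ev, "A" * 40, lib[0])


def test_every_product_satisfies_containment_identity(learned_small, small_pool):
    """I-M product = retained primer prefix + exact reverse complement of
    the template prefix — asserted for 100% of products in a real run."""
    lib = make_tag_library(300, seed=13)  # same library as the fixture
    checked = 0
    for p in learned_small.products:
        if p.provenance != "I-M":
            continue
        template = small_pool.fragments[p.template_index].sequence
        w = p.template_pos
        prefix_len = len(p.sequence) - w
        assert p.sequence[prefix_len:] == revcomp(template[:w])
        assert lib.full_sequence(p.tag_index).startswith(p.sequence[:prefix_len])
        checked += 1
    assert checked > 50


# ------------------------------------------------- digestion / separation


def test_run_learning_order_sensitivity(small_pool, small_tags):
    """Digestion before extension learns nothing; A→E→D learns plenty."""
    ade = run_learning(small_pool, small_tags, "ADE", temperature=25.0, seed=1)
    aed = run_learning(small_pool, small_tags, "AED", temperature=25.0, seed=1)
    assert len(ade) == 0
    assert classify_products(ade)["LP_H"] == 0
    assert classify_products(aed)["LP_H"] > 0


def test_run_learning_without_digestion_keeps_free_tags(small_pool, small_tags):
    """A→E retains unused tags as 40-base TAG_ONLY molecules; at 55 °C most
    tags never find a site, so skipping digestion leaves them in the pool."""
    ae = run_learning(small_pool, small_tags, "AE", temperature=55.0, seed=1)
    counts = classify_products(ae)
    assert counts["TAG_ONLY"] > 0
    aed = run_learning(small_pool, small_tags, "AED", temperature=55.0, seed=1)
    assert counts["TAG_ONLY"] > classify_products(aed)["TAG_ONLY"]


def test_run_learning_deterministic_under_seed(small_pool, small_tags):
    a = run_learning(small_pool, small_tags, "AED", temperature=25.0, seed=9)
    b = run_learning(small_pool, small_tags, "AED", temperature=25.0, seed=9)
    assert [p.sequence for p in a.products] == [p.sequence for p in b.products]


def test_run_learning_rejects_bad_order(small_pool, small_tags):
    with pytest.raises(ValueError):
        run_learning(small_pool, small_tags, "DEA", seed=0)


def test_bead_separation_equals_prefix_filter_oracle():
    """Separation keeps exactly the molecules beginning with the tag."""
    keep = LearnedProduct(DEFAULT_TAG_SEQ + "ACGT", "I-M", 0)
    tag = LearnedProduct(DEFAULT_TAG_SEQ + "A" * 20, "tag", 1)
    ii = LearnedProduct("ACGT" * 30, "I-I", -1)  # input-input, unmodified
    pool = [keep, ii, tag]
    kept = bead_separate(pool)
    assert kept == [m for m in pool if m.sequence.startswith(DEFAULT_TAG_SEQ)]
    assert ii not in kept
    assert bead_separate([ii]) == []  # input-input products never survive


def test_conservation_no_new_sequence_content(learned_small, small_pool, small_tags):
    """Products contain only tag content and input reverse complements."""
    inputs_rc = "".join(f.sequence for f in small_pool.fragments)
    for p in learned_small.products[:100]:
        if p.provenance == "I-M":
            tail = p.sequence[40:]
            if len(tail) >= 20:
                assert revcomp(tail[:20]) in inputs_rc


# ------------------------------------------------------------ by-products


def test_tag_tag_byproducts_lengths_bounded(small_tags):
    """All tag-tag extension product lengths lie within [5, 80]."""
    lengths = tag_tag_byproducts(small_tags, temperature=25.0)
    assert len(lengths) > 0
    assert lengths.min() >= 5 and lengths.max() <= 80
    # the model geometry is tighter still: 25 <= length <= 75
    assert lengths.min() >= 25 and lengths.max() <= 75


def test_tag_tag_byproducts_empty_without_complementary_windows():
    lib = make_tags_from_probes(["A" * 20, "A" * 20])
    assert len(tag_tag_byproducts(lib, temperature=25.0)) == 0


def test_tag_tag_byproducts_designed_overlap_geometry():
    """Two tags with a single engineered 6-base 3' overlap: the primer keeps
    34 bases (6-base tail trimmed... none here: duplex at probe start) and
    copies the partner's 34 upstream bases — length 74, symmetric pair."""
    x = "A" * 14 + "GGCGGC"
    y = "A" * 14 + "GCCGCC"
    lib = make_tags_from_probes([x, y])
    lengths = tag_tag_byproducts(lib, temperature=25.0)
    # primer x pairs its last 6 bases (p=34, d=6) at partner position w=34:
    # product length = (34 + 6) + 34 = 74; same for y on x.
    assert lengths.tolist() == [74, 74]


def test_negative_control_never_yields_lp_h(small_tags):
    """Tags-only learning yields no >80-base products at any temperature."""
    empty = FragmentPool([], label="none")
    for temp in (25.0, 40.0, 55.0):
        lp = run_learning(empty, small_tags, "AED", temperature=temp, seed=3)
        assert classify_products(lp)["LP_H"] == 0


# --------------------------------------------------------- classification


@pytest.mark.parametrize(
    "length,cls",
    [(30, "SUB_TAG"), (40, "TAG_ONLY"), (41, "SHORT"), (80, "SHORT"), (81, "LP_H"), (92, "LP_H")],
)
def test_length_classes(length, cls):
    assert learning.classify_length(length) == cls


def test_classify_counts_partition_pool(learned_small):
    counts = classify_products(learned_small)
    total = counts["SUB_TAG"] + counts["TAG_ONLY"] + counts["SHORT"] + counts["LP_H"]
    assert total == len(learned_small)
    assert counts["LP_S"] <= counts["SHORT"]


# -------------------------------------------------------------- screening


def test_nch_screen_detects_planted_complement():
    pool = FragmentPool([frag("TT" + revcomp(DEFAULT_TAG_SEQ) + "AA")])
    rep = nch_screen(DEFAULT_TAG_SEQ, pool, temperature=25.0)
    assert rep["longest_match"] == 20
    assert rep["stable"] and not rep["passed"]


def test_nch_screen_matches_quadratic_oracle():
    rng = np.random.default_rng(11)
    seqs = ["".join(rng.choice(list("ACGT"), 600)) for _ in range(3)]
    pool = FragmentPool([frag(s) for s in seqs])
    rep = nch_screen(DEFAULT_TAG_SEQ, pool, temperature=25.0)
    rc = revcomp(DEFAULT_TAG_SEQ)
    best = 0
    for s in seqs:
        for d in range(1, 21):
            for i in range(0, 21 - d):
                if rc[i : i + d] in s:
                    best = max(best, d)
    assert rep["longest_match"] == best


def test_nch_screen_empty_pool_passes():
    rep = nch_screen(DEFAULT_TAG_SEQ, FragmentPool([]), temperature=25.0)
    assert rep["longest_match"] == 0 and rep["passed"]


# ------------------------------------------------------------------ FASTA


def test_learned_pool_fasta_round_trip(tmp_path, learned_small):
    path = tmp_path / "learned.fasta"
    learning.write_learned_fasta(learned_small, path)
    back = learning.read_learned_fasta(path)
    assert len(back) == len(learned_small)
    for a, b in zip(learned_small.products, back.products):
        assert (a.sequence, a.provenance, a.tag_index) == (
            b.sequence,
            b.provenance,
            b.tag_index,
        )
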