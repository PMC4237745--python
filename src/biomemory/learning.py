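"""The in vitro learning protocol, simulated.

A memory tag is a 40-nt oligo: a fixed 20-base non-crosshybridizing
(NCH) tag with a 5' modification, followed by a 20-base random probe
(R20).  Learning proceeds through annealing (A) of probes to denatured
input fragments, Klenow extension (E) — which first trims the primer's
unpaired 3' tail back to the duplex and then copies the template to its
5' terminus — and Exo I digestion (D) of unbound single strands,
finishing with affinity (bead) separation of 5'-modified molecules.

Product provenance:

* ``I-M``  — tag primed on an input fragment (the desired product),
* ``M-M``  — tag primed on another tag (by-product, 25-75 nt here),
* ``tag``  — an unextended 40-nt memory tag retained by the beads.

Input-input extension products carry no 5' modification and never
survive bead separation, so they are not materialized.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import thermo
from .genome import Fragment, FragmentPool
from .matching import MatchSite, SeedIndex, enumerate_all_windows, find_sites
from .seqs import decode, encode, revcomp

DEFAULT_TAG_SEQ = "GAAAAAACACCCCTTCGATG"
PROBE_LEN = 20
TAG_LEN = 20
FULL_LEN = TAG_LEN + PROBE_LEN

VALID_ORDERS = ("AED", "ADE", "AE", "AD")


@dataclass(frozen=True)
class MemoryTag:
    """One memory oligo: fixed NCH tag + one concrete draw of R20."""

    tag_seq: str
    probe_seq: str
    modification: str = "biotin"

    def __post_init__(self) -> None:
        if len(self.tag_seq) != TAG_LEN or len(self.probe_seq) != PROBE_LEN:
            raise ValueError("tag and probe must each be 20 bases")
        if self.modification not in ("biotin", "amine"):
            raise ValueError("modification must be 'biotin' or 'amine'")

    @property
    def full_sequence(self) -> str:
        return self.tag_seq + self.probe_seq


class TagLibrary:
    """A library of memory tags sharing one NCH tag sequence.

    Probe sequences are stored as a packed (n, 20) code matrix so large
    libraries stay cheap; individual :class:`MemoryTag` objects are
    materialized on demand.
    """

    def __init__(self, tag_seq: str, probes: np.ndarray, modification: str, seed: int):
        if len(tag_seq) != TAG_LEN:
            raise ValueError("tag_seq must be 20 bases")
        self.tag_seq = tag_seq
        self.probes = probes
        self.modification = modification
        self.seed = seed
        self._tag_codes = encode(tag_seq)

    def __len__(self) -> int:
        return self.probes.shape[0]

    def __getitem__(self, i: int) -> MemoryTag:
        return MemoryTag(self.tag_seq, decode(self.probes[i]), self.modification)

    def probe_seq(self, i: int) -> str:
        return decode(self.probes[i])

    def full_sequence(self, i: int) -> str:
        return self.tag_seq + self.probe_seq(i)

    def full_codes(self, i: int) -> np.ndarray:
        return np.concatenate([self._tag_codes, self.probes[i]])

    @property
    def design_space(self) -> int:
        """Number of distinct possible probe sequences (4**20)."""
        return 4**PROBE_LEN


def make_tag_library(
    n: int,
    seed: int = 0,
    tag_seq: str = DEFAULT_TAG_SEQ,
    modification: str = "biotin",
) -> TagLibrary:
    """Draw ``n`` memory tags with i.i.d. uniform random probes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    probes = rng.integers(0, 4, size=(n, PROBE_LEN), dtype=np.int64).astype(np.uint8)
    return TagLibrary(tag_seq, probes, modification, seed)


@dataclass(frozen=True)
class AnnealingEvent:
    """A primer-template duplex chosen for one tag.

    ``p`` and ``d`` locate the paired probe bases within the 40-mer
    (0-based, p >= 20 since only R20 may pair); ``template_pos`` is the
    number of template bases 5' of the duplex — the bases that will be
    copied during extension.
    """

    tag_index: int
    template_kind: str  # 'fragment' or 'tag'
    template_index: int
    p: int
    d: int
    template_pos: int
    tm: float
    dh: float = 0.0  # NN enthalpy sum of the duplex window, kcal/mol
    ds: float = 0.0  # NN entropy sum, cal/mol/K

    def __post_init__(self) -> None:
        if self.p < TAG_LEN or self.p + self.d > FULL_LEN:
            raise ValueError("only the R20 region may pair (p >= 20, p + d <= 40)")


@dataclass(frozen=True)
class LearnedProduct:
    """A single-stranded product retained after the protocol."""

    sequence: str
    provenance: str  # 'I-M', 'M-M', or 'tag'
    tag_index: int
    template_kind: str | None = None
    template_index: int | None = None
    template_pos: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length_class(self) -> str:
        return classify_length(len(self.sequence))


@dataclass
class LearnedPool:
    """Bead-separated products plus run metadata."""

    products: list[LearnedProduct]
    label: str = "learned"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.products)


def classify_length(length: int) -> str:
    """Gel length classes: 40-base tag, short products, high-MW products."""
    if length < FULL_LEN:
        return "SUB_TAG"
    if length == FULL_LEN:
        return "TAG_ONLY"
    if length <= 80:
        return "SHORT"
    return "LP_H"


def classify_products(pool: LearnedPool) -> dict[str, int]:
    """Counts per length class; ``LP_S`` is the 50-80 nt sub-bin of SHORT."""
    counts = {"SUB_TAG": 0, "TAG_ONLY": 0, "SHORT": 0, "LP_H": 0, "LP_S": 0}
    for prod in pool.products:
        cls = prod.length_class
        counts[cls] += 1
        if cls == "SHORT" and 50 <= len(prod) <= 80:
            counts["LP_S"] += 1
        if cls == "SUB_TAG" and prod.provenance not in ("I-M", "M-M"):
            raise ValueError("only trimmed extension products may be shorter than 40")
    return counts


def _site_to_event(site: MatchSite, kind: str, template_offset: int = 0) -> AnnealingEvent:
    """Convert a probe-region match site into an annealing event.

    The matcher works on revcomp(probe) coordinates; a site at q_start a
    with length d pairs probe bases [20 - a - d, 20 - a) of R20, i.e.
    p = 40 - a - d in 40-mer coordinates.
    """
    return AnnealingEvent(
        tag_index=site.query_index,
        template_kind=kind,
        template_index=site.template_index - template_offset,
        p=FULL_LEN - site.q_start - site.length,
        d=site.length,
        template_pos=site.t_start,
        tm=site.tm,
        dh=site.dh,
        ds=site.ds,
    )


def enumerate_annealing_sites(
    tags: TagLibrary,
    pool: FragmentPool,
    temperature: float,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    k_min: int = 5,
    all_windows: bool = False,
) -> list[AnnealingEvent]:
    """All qualifying probe-template duplex windows, before sampling.

    With ``all_windows=True`` every qualifying (p, d, template_pos)
    triple is returned, sub-windows of longer matches included (the
    exhaustive enumeration contract); otherwise one entry per maximal
    match.
    """
    queries = [tags.probes[i] for i in range(len(tags))]
    templates = [encode(f.sequence) for f in pool.fragments]
    if all_windows:
        sites = enumerate_all_windows(queries, templates, temperature, cond, k_min)
    else:
        sites = find_sites(queries, SeedIndex(templates), temperature, cond, k_min)
    return [_site_to_event(s, "fragment") for s in sites]


def _candidate_sites(
    tags: TagLibrary,
    fragment_templates: list[np.ndarray],
    tag_templates: list[np.ndarray],
    temperature: float,
    cond: thermo.DuplexConditions,
    k_min: int,
) -> list[AnnealingEvent]:
    """Maximal admissible sites on fragments and (optionally) on tags."""
    queries = [tags.probes[i] for i in range(len(tags))]
    templates = fragment_templates + tag_templates
    sites = find_sites(queries, SeedIndex(templates), temperature, cond, k_min)
    n_frag = len(fragment_templates)
    events = []
    for s in sites:
        if s.template_index < n_frag:
            events.append(_site_to_event(s, "fragment"))
        else:
            events.append(_site_to_event(s, "tag", template_offset=n_frag))
    return events


def _sample_events(
    events: list[AnnealingEvent],
    temperature: float,
    rng: np.random.Generator,
) -> list[AnnealingEvent]:
    """One site per tag, Boltzmann-weighted, with exclusive occupancy.

    Site weights are exp(-ΔG°/RT) with ΔG° = ΔH - T·ΔS of the duplex
    window at the annealing temperature (longer, more stable windows
    are exponentially preferred).  Tags are processed in seeded random
    order; a template interval already occupied by an earlier primer is
    unavailable.
    """
    by_tag: dict[int, list[AnnealingEvent]] = {}
    for ev in events:
        by_tag.setdefault(ev.tag_index, []).append(ev)
    occupied: dict[tuple[str, int], list[tuple[int, int]]] = {}

    def free(ev: AnnealingEvent) -> bool:
        ivals = occupied.get((ev.template_kind, ev.template_index), ())
        lo, hi = ev.template_pos, ev.template_pos + ev.d
        return all(hi <= s or lo >= e for s, e in ivals)

    chosen: list[AnnealingEvent] = []
    order = list(by_tag)
    rng.shuffle(order)
    beta = 1.0 / (thermo.R_GAS * (temperature + thermo.CELSIUS))
    for tag_idx in order:
        cands = [ev for ev in by_tag[tag_idx] if free(ev)]
        if not cands:
            continue
        # stability score: duplex ΔG° at T from the NN sums of the window
        t_k = temperature + thermo.CELSIUS
        logits = np.array(
            [-(ev.dh * 1000.0 - t_k * ev.ds) * beta for ev in cands]
        )
        logits -= logits.max()
        w = np.exp(logits)
        ev = cands[rng.choice(len(cands), p=w / w.sum())]
        chosen.append(ev)
        occupied.setdefault((ev.template_kind, ev.template_index), []).append(
            (ev.template_pos, ev.template_pos + ev.d)
        )
    chosen.sort(key=lambda e: (e.tag_index, e.template_kind, e.template_index))
    return chosen


def anneal(
    tags: TagLibrary,
    pool: FragmentPool,
    temperature: float,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    k_min: int = 5,
    seed: int = 0,
) -> list[AnnealingEvent]:
    """Anneal tag probes to a fragment pool: one stability-weighted,
    exclusively-occupying site per tag."""
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    templates = [encode(f.sequence) for f in pool.fragments]
    events = _candidate_sites(tags, templates, [], temperature, cond, k_min)
    return _sample_events(events, temperature, np.random.default_rng(seed))


def klenow_extend(
    event: AnnealingEvent,
    template: Fragment | MemoryTag | str,
    primer: MemoryTag | str,
) -> LearnedProduct:
    """Trim the primer's unpaired 3' tail, then copy the template 5' region.

    The product is the retained primer prefix (bases [0, p + d)) plus
    the reverse complement of the template bases 5' of the duplex.
    """
    tseq = template if isinstance(template, str) else (
        template.sequence if isinstance(template, Fragment) else template.full_sequence
    )
    pseq = primer if isinstance(primer, str) else primer.full_sequence
    w = event.template_pos
    if pseq[event.p : event.p + event.d] != revcomp(tseq[w : w + event.d]):
        raise ValueError("event window is not an exact complement of the template")
    product_seq = pseq[: event.p + event.d] + revcomp(tseq[:w])
    provenance = "I-M" if event.template_kind == "fragment" else "M-M"
    return LearnedProduct(
        sequence=product_seq,
        provenance=provenance,
        tag_index=event.tag_index,
        template_kind=event.template_kind,
        template_index=event.template_index,
        template_pos=w,
    )


@dataclass
class ReactionState:
    """Molecule bookkeeping across protocol steps."""

    tags: TagLibrary
    pool: FragmentPool
    events: list[AnnealingEvent] = field(default_factory=list)
    products: list[LearnedProduct] = field(default_factory=list)
    free_tags: set[int] = field(default_factory=set)
    template_tags: set[int] = field(default_factory=set)  # tags bound as templates
    digested: bool = False


def exo_digest(state: ReactionState) -> ReactionState:
    """Exo I digestion of single-stranded molecules.

    Extended products and their bound templates are duplex-protected.
    Unextended primer-template anchors do not survive the digestion
    incubation (their Tm is generally below the 37 °C reaction
    temperature), so annealed-but-unextended complexes dissolve and are
    digested together with free tags and free input strands.
    """
    state.events = []
    state.free_tags = set()
    state.digested = True
    return state


def bead_separate(
    molecules: list[LearnedProduct], tag_seq: str = DEFAULT_TAG_SEQ
) -> list[LearnedProduct]:
    """Retain molecules whose 5' end begins with the modified NCH tag."""
    return [m for m in molecules if m.sequence.startswith(tag_seq)]


def run_learning(
    pool: FragmentPool,
    tags: TagLibrary,
    order: str = "AED",
    temperature: float = 25.0,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    k_min: int = 5,
    seed: int = 0,
    include_tag_templates: bool = True,
) -> LearnedPool:
    """Execute the protocol steps in ``order``; bead separation is last.

    ``order`` must be one of AED, ADE, AE, AD.  The canonical A→E→D run
    yields input-templated products (I-M) plus tag-tag by-products
    (M-M); running digestion before extension destroys the unextended
    complexes, so A→D(→E) learns nothing.
    """
    if order not in VALID_ORDERS:
        raise ValueError(f"order must be one of {VALID_ORDERS}")
    rng = np.random.default_rng(seed)
    frag_templates = [encode(f.sequence) for f in pool.fragments]
    tag_templates = (
        [tags.full_codes(i) for i in range(len(tags))] if include_tag_templates else []
    )
    candidates = _candidate_sites(
        tags, frag_templates, tag_templates, temperature, cond, k_min
    )
    state = ReactionState(tags=tags, pool=pool, free_tags=set(range(len(tags))))
    state.events = _sample_events(candidates, temperature, rng)
    for ev in state.events:
        state.free_tags.discard(ev.tag_index)
        if ev.template_kind == "tag":
            state.template_tags.add(ev.template_index)

    for step in order[1:]:
        if step == "E":
            for ev in state.events:
                template = (
                    pool.fragments[ev.template_index]
                    if ev.template_kind == "fragment"
                    else tags.full_sequence(ev.template_index)
                )
                state.products.append(
                    klenow_extend(ev, template, tags.full_sequence(ev.tag_index))
                )
            state.events = []
        elif step == "D":
            if state.products:
                # template tags of extended complexes stay duplex-protected
                protected = {
                    p.template_index
                    for p in state.products
                    if p.template_kind == "tag"
                }
            else:
                protected = set()
            state.template_tags &= protected
            exo_digest(state)

    molecules = list(state.products)
    for i in sorted(state.free_tags | state.template_tags):
        molecules.append(
            LearnedProduct(sequence=tags.full_sequence(i), provenance="tag", tag_index=i)
        )
    kept = bead_separate(molecules, tags.tag_seq)
    counts = {}
    for m in kept:
        counts[m.provenance] = counts.get(m.provenance, 0) + 1
    return LearnedPool(
        products=kept,
        label=pool.label,
        metadata={
            "order": order,
            "temperature": temperature,
            "seed": seed,
            "n_tags": len(tags),
            "tag_seq": tags.tag_seq,
            "k_min": k_min,
            "mixture": pool.mixture,
            "provenance_counts": counts,
        },
    )


def tag_tag_byproducts(
    tags: TagLibrary,
    temperature: float = 25.0,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    k_min: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Lengths of all possible tag-tag extension by-products.

    Enumerates maximal stable pairings of each tag's probe 3' region on
    every tag (as template), applies the trim-and-extend rule with the
    partner as template, and returns the product length multiset.  The
    geometry bounds every length to [25, 75] ⊂ [5, 80]: the retained
    primer prefix is 25-40 nt and the copied template 5' region at most
    40 - d nt.
    """
    queries = [tags.probes[i] for i in range(len(tags))]
    templates = [tags.full_codes(i) for i in range(len(tags))]
    sites = find_sites(queries, SeedIndex(templates), temperature, cond, k_min)
    lengths = []
    for s in sites:
        ev = _site_to_event(s, "tag")
        prod = klenow_extend(
            ev, tags.full_sequence(ev.template_index), tags.full_sequence(ev.tag_index)
        )
        lengths.append(len(prod))
    return np.array(sorted(lengths), dtype=int)


def write_learned_fasta(pool: LearnedPool, path) -> None:
    """Serialize a learned pool; provenance is kept in the headers."""
    with open(path, "w") as fh:
        for i, p in enumerate(pool.products):
            fh.write(
                f">lp{i} {p.provenance}|tag{p.tag_index}|{p.length_class}"
                f"|{p.template_kind or '.'}|{p.template_index if p.template_index is not None else '.'}\n"
            )
            for j in range(0, len(p.sequence), 80):
                fh.write(p.sequence[j : j + 80] + "\n")


def read_learned_fasta(path, label: str = "learned") -> LearnedPool:
    from Bio import SeqIO

    products = []
    for rec in SeqIO.parse(str(path), "fasta"):
        prov, tag, _cls, kind, tidx = rec.description.split(" ", 1)[1].split("|")
        products.append(
            LearnedProduct(
                sequence=str(rec.seq).upper(),
                provenance=prov,
                tag_index=int(tag.removeprefix("tag")),
                template_kind=None if kind == "." else kind,
                template_index=None if tidx == "." else int(tidx),
            )
        )
    return LearnedPool(products, label=label)


def nch_screen(
    tag_seq: str,
    pool: FragmentPool,
    cond: thermo.DuplexConditions = thermo.LEARNING_CONDITIONS,
    temperature: float = 25.0,
) -> dict:
    """Longest complementary match of the NCH tag anywhere in a pool.

    A guard, not a design procedure: reports the longest window of
    ``tag_seq`` whose exact complement occurs in the pool and whether
    that duplex would be stable at ``temperature``.
    """
    rc = encode(revcomp(tag_seq))
    templates = [encode(f.sequence) for f in pool.fragments]
    best_d, best_tm = 0, None
    # longest common run between revcomp(tag) and any template, found by
    # shrinking window sets
    from .seqs import kmer_codes

    for d in range(len(tag_seq), 0, -1):
        probe_codes = set(kmer_codes(rc, d).tolist())
        hit = None
        for t in templates:
            tc = kmer_codes(t, d)
            mask = np.isin(tc, list(probe_codes))
            if mask.any():
                pos = int(np.flatnonzero(mask)[0])
                hit = t[pos : pos + d]
                break
        if hit is not None:
            best_d = d
            best_tm = (
                float(thermo.tm_array(hit[None, :], cond)[0]) if d >= 2 else None
            )
            break
    stable = best_tm is not None and best_tm >= temperature
    return {
        "tag_seq": tag_seq,
        "longest_match": best_d,
        "tm": best_tm,
        "temperature": temperature,
        "stable": bool(stable),
        "passed": not stable,
    }
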