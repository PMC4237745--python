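"""Exact-complement window search between probe strands and templates.

The learning and recall steps both reduce to the same primitive: given a
set of single-stranded queries and a set of single-stranded templates,
find every maximal window where a query substring is the exact reverse
complement of a template substring, and keep the windows whose duplex
melting temperature reaches the reaction temperature.

The search is seed-and-extend on 2-bit packed window codes.  The seed
length adapts to the temperature: below the admissibility floor
k* = min_stable_anchor_length(T, stat='max') no window of any
composition is stable, so nothing shorter than k* is ever searched.
Window lengths in [k*, seed_len) are caught by auxiliary passes that
query only probe windows whose own Tm reaches T (precomputed Tm lookup
tables over all 4^d d-mers, d <= 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import thermo
from .seqs import COMPLEMENT, enumerate_kmers, kmer_codes


@dataclass(frozen=True)
class MatchSite:
    """A maximal exact-complement window between a query and a template.

    ``q_start`` indexes the *reverse complement* of the query strand;
    ``t_start`` the template 5'→3'.  ``length`` bases of
    revcomp(query)[q_start:] equal template[t_start:t_start+length].
    """

    query_index: int
    template_index: int
    q_start: int
    t_start: int
    length: int
    tm: float
    dh: float = 0.0  # kcal/mol NN sum of the window duplex
    ds: float = 0.0  # cal/mol/K


@lru_cache(maxsize=32)
def _tm_code_table(d: int, cond_key: tuple, params_name: str) -> np.ndarray:
    """Tm of every d-mer duplex, indexed by packed code (d <= 10)."""
    cond = thermo.DuplexConditions(*cond_key)
    params = {p.name: p for p in (thermo.SANTALUCIA_1998,)}[params_name]
    return thermo.tm_array(enumerate_kmers(d), cond, params)


def _cond_key(cond: thermo.DuplexConditions) -> tuple:
    return (cond.strand_conc, cond.na, cond.mg, cond.dntp, cond.temperature)


class SeedIndex:
    """Sorted-code index over template sequences for several seed lengths."""

    def __init__(self, templates: list[np.ndarray]):
        self.templates = templates
        self._by_len: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _build(self, L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        codes, tids, poss = [], [], []
        for tid, t in enumerate(self.templates):
            c = kmer_codes(t, L)
            if c.size:
                codes.append(c)
                tids.append(np.full(c.size, tid, dtype=np.int32))
                poss.append(np.arange(c.size, dtype=np.int32))
        if not codes:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty.astype(np.int32), empty.astype(np.int32)
        codes = np.concatenate(codes)
        tids = np.concatenate(tids)
        poss = np.concatenate(poss)
        order = np.argsort(codes, kind="stable")
        return codes[order], tids[order], poss[order]

    def lookup(
        self, L: int, query_codes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All template hits of ``query_codes``.

        Returns (query_row, template_id, template_pos) arrays, one entry
        per occurrence.
        """
        if L not in self._by_len:
            self._by_len[L] = self._build(L)
        codes, tids, poss = self._by_len[L]
        lo = np.searchsorted(codes, query_codes, side="left")
        hi = np.searchsorted(codes, query_codes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        qrow = np.repeat(np.arange(query_codes.size), counts)
        # flat indices into the sorted arrays for each hit
        starts = np.repeat(lo, counts)
        offsets = np.arange(total) - np.repeat(
            np.concatenate(([0], np.cumsum(counts)[:-1])), counts
        )
        flat = starts + offsets
        return qrow, tids[flat].astype(np.int64), poss[flat].astype(np.int64)


def _seed_plan(k_star: int, max_query_len: int) -> tuple[int, list[int]]:
    """Choose the main seed length and the short auxiliary pass lengths."""
    if k_star >= 11:
        seed_len = min(k_star, max_query_len)
        short = []
    else:
        seed_len = min(k_star + 3, 11, max_query_len)
        short = [d for d in range(k_star, seed_len)]
    return seed_len, short


def find_sites(
    queries: list[np.ndarray],
    index: SeedIndex,
    temperature: float,
    cond: thermo.DuplexConditions,
    k_min: int = 5,
    params: thermo.NNParameterSet = thermo.SANTALUCIA_1998,
    require_stable: bool = True,
) -> list[MatchSite]:
    """Maximal exact-complement windows with Tm >= ``temperature``.

    ``queries`` are plain 5'→3' code arrays; matching is performed
    against their reverse complements so that a site corresponds to a
    physical antiparallel duplex with a template.

    With ``require_stable=False`` every maximal run long enough to
    possibly contain a stable window is returned, without the final
    full-window Tm filter (used by the exhaustive window enumeration,
    where stability is decided per sub-window).
    """
    k_star = max(
        k_min,
        thermo.min_stable_anchor_length(temperature, cond, stat="max", params=params),
    )
    rc_queries = [COMPLEMENT[q][::-1] for q in queries]
    max_qlen = max((q.size for q in queries), default=0)
    if max_qlen < k_star or not index.templates:
        return []
    seed_len, short_lengths = _seed_plan(k_star, max_qlen)

    # per (query, template, diagonal): intervals already covered by a
    # maximal run, so repeated seed hits along a long run extend it once
    runs: dict[tuple[int, int, int], list[tuple[int, int]]] = {}
    # accumulated candidate sites grouped by window length
    cand: dict[int, list[tuple[int, int, int, int]]] = {}

    def window_codes(L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        codes, qidx, qpos = [], [], []
        for qi, rq in enumerate(rc_queries):
            c = kmer_codes(rq, L)
            if c.size:
                codes.append(c)
                qidx.append(np.full(c.size, qi, dtype=np.int64))
                qpos.append(np.arange(c.size, dtype=np.int64))
        if not codes:
            e = np.empty(0, dtype=np.int64)
            return e, e, e
        return np.concatenate(codes), np.concatenate(qidx), np.concatenate(qpos)

    def extend_and_record(qi: int, a: int, tid: int, w: int, L: int, short: bool):
        key = (qi, tid, w - a)
        ivals = runs.get(key)
        if ivals is not None and any(s <= a < e for s, e in ivals):
            return  # this run was already extended from another seed hit
        rq = rc_queries[qi]
        t = index.templates[tid]
        left = 0
        while a - left - 1 >= 0 and w - left - 1 >= 0 and rq[a - left - 1] == t[w - left - 1]:
            left += 1
        right = 0
        while (
            a + L + right < rq.size
            and w + L + right < t.size
            and rq[a + L + right] == t[w + L + right]
        ):
            right += 1
        a0, w0, m = a - left, w - left, L + left + right
        runs.setdefault(key, []).append((a0, a0 + m))
        if short and m >= seed_len:
            return  # any run this long contains a seed window: main pass has it
        cand.setdefault(m, []).append((qi, a0, tid, w0))

    # main pass: all query windows at the seed length
    codes, qidx, qpos = window_codes(seed_len)
    if codes.size:
        rows, tids, poss = index.lookup(seed_len, codes)
        for r, tid, w in zip(rows, tids, poss):
            extend_and_record(int(qidx[r]), int(qpos[r]), int(tid), int(w), seed_len, False)

    # short passes: only windows that are themselves stable at T
    ckey, pname = _cond_key(cond), params.name
    for d in short_lengths:
        codes, qidx, qpos = window_codes(d)
        if not codes.size:
            continue
        table = _tm_code_table(d, ckey, pname)
        ok = table[codes] >= temperature
        if not ok.any():
            continue
        rows, tids, poss = index.lookup(d, codes[ok])
        qidx_ok, qpos_ok = qidx[ok], qpos[ok]
        for r, tid, w in zip(rows, tids, poss):
            extend_and_record(int(qidx_ok[r]), int(qpos_ok[r]), int(tid), int(w), d, True)

    # batch Tm of the maximal windows, keep those stable at T
    sites: list[MatchSite] = []
    for m, entries in cand.items():
        if m < k_star:
            continue
        mat = np.empty((len(entries), m), dtype=np.uint8)
        for i, (qi, a0, tid, w0) in enumerate(entries):
            mat[i] = index.templates[tid][w0 : w0 + m]
        tms = thermo.tm_array(mat, cond, params)
        dhs, dss = thermo._dh_ds_batch(mat, params)
        for (qi, a0, tid, w0), tm, dh, ds in zip(entries, tms, dhs, dss):
            if require_stable and tm < temperature:
                continue
            sites.append(MatchSite(qi, tid, a0, w0, m, float(tm), float(dh), float(ds)))
    sites.sort(key=lambda s: (s.query_index, s.template_index, s.t_start, s.length))
    return sites


def enumerate_all_windows(
    queries: list[np.ndarray],
    templates: list[np.ndarray],
    temperature: float,
    cond: thermo.DuplexConditions,
    k_min: int = 5,
    params: thermo.NNParameterSet = thermo.SANTALUCIA_1998,
) -> list[MatchSite]:
    """Every qualifying (query, template, window) triple, sub-windows included.

    Expands each maximal site into all contained windows of length
    >= k_min whose Tm reaches the temperature.  Intended for small
    inputs (oracle comparisons, screening); the sampled annealing path
    uses only the maximal sites.
    """
    index = SeedIndex(templates)
    out: list[MatchSite] = []
    floor = max(2, k_min)
    for site in find_sites(
        queries, index, temperature, cond, min(k_min, 2), params, require_stable=False
    ):
        t = templates[site.template_index]
        for d in range(floor, site.length + 1):
            for off in range(site.length - d + 1):
                w = site.t_start + off
                win = t[w : w + d][None, :]
                tm = float(thermo.tm_array(win, cond, params)[0])
                if tm >= temperature:
                    dh, ds = thermo._dh_ds_batch(win, params)
                    out.append(
                        MatchSite(
                            site.query_index,
                            site.template_index,
                            site.q_start + off,
                            w,
                            d,
                            tm,
                            float(dh[0]),
                            float(ds[0]),
                        )
                    )
    out.sort(key=lambda s: (s.query_index, s.template_index, s.t_start, s.length))
    return out
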