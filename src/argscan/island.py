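"""Importance-sampling estimator of the R_A fraction under island models.

The structured coalescent runs on the timescale of 2N generations of a
reference deme: within a deme of relative size ``N_d`` each lineage pair
coalesces at rate ``1/N_d``, and each lineage leaves its deme at total rate
``M/2`` (split uniformly over the other demes in the symmetric model),
where ``M = 4Nm`` is the population migration parameter on the standard
scaling.  A merge schedule can relocate
whole demes into an ancestral pool at fixed times, emulating populations
that were panmictic beyond some age.

Protocol (per accepted tree): a genealogy is simulated under the model and
retained only if a pre-chosen population is an outgroup clade; one
recombination is placed uniformly at random on its branches; the new
recombinant lineage migrates and recoalesces with the tree at the prior
rates (replaying the recorded deme occupancy of every branch); the outcome
is classified R_A / R_O / neither by the topological disruption rules, the
"neither" outcomes are discarded, and each tree is weighted by its total
branch length L(T) to correct for the fact that every accepted tree was
forced to carry exactly one recombination.

``M = infinity`` is handled as a single panmictic deme, for which the exact
closed form of :mod:`argscan.panmictic` applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

from . import panmictic

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap(args[0]) if args and callable(args[0]) else wrap

CLASS_RA, CLASS_RO, CLASS_NEITHER = 0, 1, 2


@dataclass(frozen=True)
class Demography:
    """Island-model configuration.

    ``deme_sizes`` are relative to the reference effective size; the
    migration matrix holds per-lineage rates ``mig[i, j]`` of moving from
    deme ``i`` to deme ``j`` backward in time (row sums equal ``M/2`` in
    the symmetric model).  ``merges`` is an ordered schedule of
    ``(time, source_deme, destination_deme)`` events, each relocating every
    lineage of the source deme and deactivating it; times are in coalescent
    units (use :func:`generations_to_coalescent` to convert).
    ``sample_sizes[i]`` samples are drawn from deme ``i``; sampled demes
    are the populations, named by ``labels``.
    """

    deme_sizes: tuple[float, ...]
    migration: tuple[tuple[float, ...], ...]
    sample_sizes: tuple[int, ...]
    labels: tuple[str, ...]
    merges: tuple[tuple[float, int, int], ...] = ()

    def __post_init__(self):
        d = len(self.deme_sizes)
        if len(self.sample_sizes) != d or len(self.labels) != d:
            raise ValueError("per-deme field lengths disagree")
        mig = np.asarray(self.migration, dtype=float)
        if mig.shape != (d, d):
            raise ValueError("migration matrix shape mismatch")
        if (mig < 0).any():
            raise ValueError("negative migration rate")
        if sum(self.sample_sizes) < 2 or max(self.sample_sizes) < 1:
            raise ValueError("need at least one sampled deme")
        times = [m[0] for m in self.merges]
        if any(t < 0 for t in times) or list(times) != sorted(times):
            raise ValueError("merge times must be nonnegative and ordered")

    @property
    def n_demes(self) -> int:
        return len(self.deme_sizes)

    @property
    def n_samples(self) -> int:
        return sum(self.sample_sizes)

    @property
    def populations(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.sample_sizes) if s > 0]

    def population_sizes(self) -> dict[str, int]:
        return {l: s for l, s in zip(self.labels, self.sample_sizes) if s > 0}

    @classmethod
    def symmetric_island(cls, d: int = 5, M: float = 1.0,
                         samples: tuple[int, ...] = (3, 3, 3, 2, 2),
                         labels: tuple[str, ...] | None = None,
                         merge_time: float | None = None,
                         deme_sizes: tuple[float, ...] | None = None,
                         ) -> "Demography":
        """Symmetric d-island model: per-lineage out-migration rate M/2."""
        if labels is None:
            labels = tuple(f"pop{i + 1}" for i in range(d))
        if deme_sizes is None:
            deme_sizes = (1.0,) * d
        rate = 0.5 * M / (d - 1) if d > 1 else 0.0
        mig = tuple(tuple(rate if i != j else 0.0 for j in range(d))
                    for i in range(d))
        merges: tuple = ()
        if merge_time is not None:
            merges = tuple((merge_time, i, 0) for i in range(1, d))
        return cls(deme_sizes=deme_sizes, migration=mig,
                   sample_sizes=tuple(samples), labels=labels, merges=merges)

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "deme_sizes": list(self.deme_sizes),
            "migration": [list(r) for r in self.migration],
            "sample_sizes": list(self.sample_sizes),
            "labels": list(self.labels),
            "merges": [list(m) for m in self.merges],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "Demography":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(deme_sizes=tuple(doc["deme_sizes"]),
                   migration=tuple(tuple(r) for r in doc["migration"]),
                   sample_sizes=tuple(doc["sample_sizes"]),
                   labels=tuple(doc["labels"]),
                   merges=tuple(tuple(m) for m in doc.get("merges", [])))


def generations_to_coalescent(generations: float,
                              gens_per_unit: float) -> float:
    """Convert a time in generations to coalescent units (2N_ref gens)."""
    return generations / gens_per_unit


@dataclass(frozen=True)
class ISEstimate:
    fraction_ra: float
    w_ra: float
    w_ro: float
    n_accepted: int
    n_kept: int
    n_proposals: int
    ess: float
    se: float
    seed: int

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_proposals if self.n_proposals else 0.0


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

_EV_COAL, _EV_MIG, _EV_MERGE = 0, 1, 2


@njit(cache=True)
def _island_kernel(seed, n_target, max_proposals,
                   pop_of_sample, deme_of_sample, pop_sizes,
                   deme_size, mig_ep, out_ep,
                   merge_time, merge_src, merge_dst,
                   harvest,
                   res_pop, res_class, res_w):
    """Rejection-sample outgroup-conditioned trees and propose recombinations.

    Returns (n_accepted, n_proposals).  Results land in res_* arrays.
    """
    np.random.seed(seed)
    nsam = pop_of_sample.shape[0]
    npop = pop_sizes.shape[0]
    nd = deme_size.shape[0]
    nmerge = merge_time.shape[0]
    NN = 2 * nsam
    CAP = 1_000_000

    time = np.zeros(NN)
    parent = np.full(NN, -1, np.int32)
    child1 = np.full(NN, -1, np.int32)
    child2 = np.full(NN, -1, np.int32)
    cnt = np.zeros((NN, npop), np.int32)
    tot = np.zeros(NN, np.int32)
    cur_deme = np.zeros(NN, np.int32)
    act = np.zeros(NN, np.int32)
    deme_members = np.zeros((nd, NN), np.int32)
    nd_cnt = np.zeros(nd, np.int64)
    pop_ok = np.zeros(npop, np.bool_)
    alive = np.zeros(NN, np.bool_)
    lens = np.zeros(NN)
    ev_t = np.zeros(CAP)
    ev_type = np.zeros(CAP, np.int8)
    ev_a = np.zeros(CAP, np.int32)
    ev_b = np.zeros(CAP, np.int32)
    ev_c = np.zeros(CAP, np.int32)

    n_acc = 0
    n_prop = 0
    while n_acc < n_target and n_prop < max_proposals:
        n_prop += 1
        # ---- init proposal
        for p in range(npop):
            pop_ok[p] = pop_sizes[p] >= 2
        nd_cnt[:] = 0
        for i in range(nsam):
            time[i] = 0.0
            parent[i] = -1
            for p in range(npop):
                cnt[i, p] = 0
            cnt[i, pop_of_sample[i]] = 1
            tot[i] = 1
            d = deme_of_sample[i]
            cur_deme[i] = d
            deme_members[d, nd_cnt[d]] = i
            nd_cnt[d] += 1
        nact = nsam
        nxt = nsam
        t = 0.0
        epoch = 0
        nev = 0
        failed = False
        while nact > 1:
            coal_rate = 0.0
            for d in range(nd):
                if nd_cnt[d] >= 2:
                    coal_rate += nd_cnt[d] * (nd_cnt[d] - 1) * 0.5 / deme_size[d]
            mig_rate = 0.0
            for d in range(nd):
                if nd_cnt[d] > 0:
                    mig_rate += nd_cnt[d] * out_ep[epoch, d]
            tot_rate = coal_rate + mig_rate
            t_merge = merge_time[epoch] if epoch < nmerge else 1e300
            if tot_rate <= 0.0:
                if t_merge >= 1e300:
                    failed = True
                    break
                dt = 1e300
            else:
                dt = np.random.exponential(1.0 / tot_rate)
            if t + dt >= t_merge and epoch < nmerge:
                t = t_merge
                src = merge_src[epoch]
                dst = merge_dst[epoch]
                while nd_cnt[src] > 0:
                    x = deme_members[src, nd_cnt[src] - 1]
                    nd_cnt[src] -= 1
                    cur_deme[x] = dst
                    deme_members[dst, nd_cnt[dst]] = x
                    nd_cnt[dst] += 1
                if nev < CAP:
                    ev_t[nev] = t
                    ev_type[nev] = _EV_MERGE
                    ev_a[nev] = src
                    ev_b[nev] = dst
                    nev += 1
                else:
                    failed = True
                    break
                epoch += 1
                continue
            t += dt
            if np.random.random() * tot_rate < coal_rate:
                # ---- coalescence: pick deme, then a pair
                r = np.random.random() * coal_rate
                dpick = -1
                acc = 0.0
                for d in range(nd):
                    if nd_cnt[d] >= 2:
                        acc += nd_cnt[d] * (nd_cnt[d] - 1) * 0.5 / deme_size[d]
                        if r < acc:
                            dpick = d
                            break
                if dpick < 0:
                    dpick = nd - 1
                i1 = np.random.randint(nd_cnt[dpick])
                i2 = np.random.randint(nd_cnt[dpick] - 1)
                if i2 >= i1:
                    i2 += 1
                a = deme_members[dpick, i1]
                b = deme_members[dpick, i2]
                w = nxt
                nxt += 1
                time[w] = t
                parent[w] = -1
                parent[a] = w
                parent[b] = w
                child1[w] = a
                child2[w] = b
                tot[w] = tot[a] + tot[b]
                for p in range(npop):
                    cnt[w, p] = cnt[a, p] + cnt[b, p]
                cur_deme[w] = dpick
                # remove a, b; add w in deme lists
                hi = i1 if i1 > i2 else i2
                lo = i2 if i1 > i2 else i1
                deme_members[dpick, hi] = deme_members[dpick, nd_cnt[dpick] - 1]
                nd_cnt[dpick] -= 1
                deme_members[dpick, lo] = deme_members[dpick, nd_cnt[dpick] - 1]
                nd_cnt[dpick] -= 1
                deme_members[dpick, nd_cnt[dpick]] = w
                nd_cnt[dpick] += 1
                nact -= 1
                # update per-population monophyly flags
                any_ok = False
                for p in range(npop):
                    if pop_ok[p]:
                        c = cnt[w, p]
                        if c > 0 and tot[w] > c:
                            if c < pop_sizes[p] or nact > 1:
                                pop_ok[p] = False
                    if pop_ok[p] and harvest[p]:
                        any_ok = True
                if nev < CAP:
                    ev_t[nev] = t
                    ev_type[nev] = _EV_COAL
                    ev_a[nev] = a
                    ev_b[nev] = b
                    ev_c[nev] = w
                    nev += 1
                else:
                    failed = True
                    break
                if not any_ok:
                    failed = True
                    break
            else:
                # ---- migration: pick source deme, lineage, destination
                r = np.random.random() * mig_rate
                dpick = -1
                acc = 0.0
                for d in range(nd):
                    if nd_cnt[d] > 0:
                        acc += nd_cnt[d] * out_ep[epoch, d]
                        if r < acc:
                            dpick = d
                            break
                if dpick < 0:
                    continue
                i1 = np.random.randint(nd_cnt[dpick])
                x = deme_members[dpick, i1]
                r2 = np.random.random() * out_ep[epoch, dpick]
                dest = -1
                acc = 0.0
                for e in range(nd):
                    acc += mig_ep[epoch, dpick, e]
                    if r2 < acc:
                        dest = e
                        break
                if dest < 0 or dest == dpick:
                    continue
                deme_members[dpick, i1] = deme_members[dpick, nd_cnt[dpick] - 1]
                nd_cnt[dpick] -= 1
                cur_deme[x] = dest
                deme_members[dest, nd_cnt[dest]] = x
                nd_cnt[dest] += 1
                if nev < CAP:
                    ev_t[nev] = t
                    ev_type[nev] = _EV_MIG
                    ev_a[nev] = x
                    ev_b[nev] = dest
                    nev += 1
                else:
                    failed = True
                    break
        if failed:
            continue
        root = nxt - 1
        pstar = -1
        for p in range(npop):
            if pop_ok[p] and harvest[p]:
                pstar = p
                break
        if pstar < 0:
            continue
        # ---- accepted: place one recombination uniformly on branches
        L = 0.0
        for x in range(root):
            lens[x] = time[parent[x]] - time[x]
            L += lens[x]
        r = np.random.random() * L
        bnode = root - 1
        acc = 0.0
        for x in range(root):
            acc += lens[x]
            if r < acc:
                bnode = x
                break
        t_r = time[bnode] + np.random.random() * lens[bnode]
        # ---- replay to t_r
        nd_cnt[:] = 0
        for i in range(nsam):
            alive[i] = True
            d = deme_of_sample[i]
            cur_deme[i] = d
            deme_members[d, nd_cnt[d]] = i
            nd_cnt[d] += 1
        for i in range(nsam, NN):
            alive[i] = False
        epoch = 0
        ptr = 0

        # helper-free inline replay of one event (numba: no closures)
        while ptr < nev and ev_t[ptr] <= t_r:
            et = ev_type[ptr]
            if et == _EV_COAL:
                a = ev_a[ptr]
                b2 = ev_b[ptr]
                w = ev_c[ptr]
                da = cur_deme[a]
                # remove a and b2 from their deme lists
                for rm in (a, b2):
                    drm = cur_deme[rm]
                    for ii in range(nd_cnt[drm]):
                        if deme_members[drm, ii] == rm:
                            deme_members[drm, ii] = deme_members[drm, nd_cnt[drm] - 1]
                            nd_cnt[drm] -= 1
                            break
                    alive[rm] = False
                alive[w] = True
                cur_deme[w] = da
                deme_members[da, nd_cnt[da]] = w
                nd_cnt[da] += 1
            elif et == _EV_MIG:
                x = ev_a[ptr]
                dest = ev_b[ptr]
                if alive[x]:
                    drm = cur_deme[x]
                    for ii in range(nd_cnt[drm]):
                        if deme_members[drm, ii] == x:
                            deme_members[drm, ii] = deme_members[drm, nd_cnt[drm] - 1]
                            nd_cnt[drm] -= 1
                            break
                    cur_deme[x] = dest
                    deme_members[dest, nd_cnt[dest]] = x
                    nd_cnt[dest] += 1
            else:  # merge
                src = ev_a[ptr]
                dst = ev_b[ptr]
                while nd_cnt[src] > 0:
                    x = deme_members[src, nd_cnt[src] - 1]
                    nd_cnt[src] -= 1
                    cur_deme[x] = dst
                    deme_members[dst, nd_cnt[dst]] = x
                    nd_cnt[dst] += 1
                epoch += 1
            ptr += 1
        # ---- float the recombinant lineage
        f = cur_deme[bnode]
        t = t_r
        partner = -2  # -2: undecided, -1: beyond root
        guard = 0
        while partner == -2:
            guard += 1
            if guard > 10_000_000:
                partner = -3
                break
            coal_f = nd_cnt[f] / deme_size[f]
            mig_f = out_ep[epoch, f]
            tot_rate = coal_f + mig_f
            t_next = ev_t[ptr] if ptr < nev else 1e300
            if tot_rate <= 0.0:
                dt = 1e300
            else:
                dt = np.random.exponential(1.0 / tot_rate)
            if t + dt >= t_next:
                if ptr >= nev:
                    break  # beyond-root phase below
                et = ev_type[ptr]
                if et == _EV_COAL:
                    a = ev_a[ptr]
                    b2 = ev_b[ptr]
                    w = ev_c[ptr]
                    da = cur_deme[a]
                    for rm in (a, b2):
                        drm = cur_deme[rm]
                        for ii in range(nd_cnt[drm]):
                            if deme_members[drm, ii] == rm:
                                deme_members[drm, ii] = deme_members[drm, nd_cnt[drm] - 1]
                                nd_cnt[drm] -= 1
                                break
                        alive[rm] = False
                    alive[w] = True
                    cur_deme[w] = da
                    deme_members[da, nd_cnt[da]] = w
                    nd_cnt[da] += 1
                elif et == _EV_MIG:
                    x = ev_a[ptr]
                    dest = ev_b[ptr]
                    if alive[x]:
                        drm = cur_deme[x]
                        for ii in range(nd_cnt[drm]):
                            if deme_members[drm, ii] == x:
                                deme_members[drm, ii] = deme_members[drm, nd_cnt[drm] - 1]
                                nd_cnt[drm] -= 1
                                break
                        cur_deme[x] = dest
                        deme_members[dest, nd_cnt[dest]] = x
                        nd_cnt[dest] += 1
                else:
                    src = ev_a[ptr]
                    dst = ev_b[ptr]
                    while nd_cnt[src] > 0:
                        x = deme_members[src, nd_cnt[src] - 1]
                        nd_cnt[src] -= 1
                        cur_deme[x] = dst
                        deme_members[dst, nd_cnt[dst]] = x
                        nd_cnt[dst] += 1
                    if f == src:
                        f = dst
                    epoch += 1
                t = t_next
                ptr += 1
                continue
            t += dt
            if np.random.random() * tot_rate < coal_f:
                partner = deme_members[f, np.random.randint(nd_cnt[f])]
            else:
                r2 = np.random.random() * out_ep[epoch, f]
                dest = -1
                acc = 0.0
                for e in range(nd):
                    acc += mig_ep[epoch, f, e]
                    if r2 < acc:
                        dest = e
                        break
                if dest >= 0:
                    f = dest
        if partner == -2:
            # beyond the grand MRCA: chase the single stem lineage
            s = cur_deme[root]
            guard = 0
            ok = True
            while True:
                guard += 1
                if guard > 10_000_000:
                    ok = False
                    break
                coal_f = (1.0 / deme_size[f]) if f == s else 0.0
                rate = coal_f + out_ep[epoch, f] + out_ep[epoch, s]
                t_merge = merge_time[epoch] if epoch < nmerge else 1e300
                if rate <= 0.0:
                    if t_merge >= 1e300:
                        ok = False
                        break
                    dt = 1e300
                else:
                    dt = np.random.exponential(1.0 / rate)
                if t + dt >= t_merge and epoch < nmerge:
                    t = t_merge
                    if f == merge_src[epoch]:
                        f = merge_dst[epoch]
                    if s == merge_src[epoch]:
                        s = merge_dst[epoch]
                    epoch += 1
                    continue
                t += dt
                r = np.random.random() * rate
                if r < coal_f:
                    partner = -1
                    break
                elif r < coal_f + out_ep[epoch, f]:
                    r2 = np.random.random() * out_ep[epoch, f]
                    acc = 0.0
                    for e in range(nd):
                        acc += mig_ep[epoch, f, e]
                        if r2 < acc:
                            f = e
                            break
                else:
                    r2 = np.random.random() * out_ep[epoch, s]
                    acc = 0.0
                    for e in range(nd):
                        acc += mig_ep[epoch, s, e]
                        if r2 < acc:
                            s = e
                            break
            if not ok:
                continue  # pathological: drop proposal entirely
        if partner == -3:
            continue
        # ---- classify
        ncl = pop_sizes[pstar]
        ntot = nsam
        cb = cnt[bnode, pstar]
        tb = tot[bnode]
        is_ra = tb == cb
        if partner == root:
            partner = -1  # joining the stem above its formation = beyond root
        if partner == bnode:
            klass = CLASS_NEITHER
        elif partner == -1:
            if is_ra:
                klass = CLASS_RA if cb < ncl else CLASS_NEITHER
            else:
                klass = CLASS_RO if tb < ntot - ncl else CLASS_NEITHER
        else:
            cx = cnt[partner, pstar]
            tx = tot[partner]
            if is_ra:
                if cx == tx and cx > 0:
                    klass = CLASS_NEITHER
                elif cb == ncl and cx == 0 and tx == ntot - ncl:
                    klass = CLASS_NEITHER
                else:
                    klass = CLASS_RA
            else:
                if cx == 0:
                    klass = CLASS_NEITHER
                elif tb == ntot - ncl and cx == ncl:
                    klass = CLASS_NEITHER
                else:
                    klass = CLASS_RO
        res_pop[n_acc] = pstar
        res_class[n_acc] = klass
        res_w[n_acc] = L
        n_acc += 1
    return n_acc, n_prop


# ---------------------------------------------------------------------------
# wrapper API
# ---------------------------------------------------------------------------

def _epoch_matrices(demography: Demography):
    """Per-epoch migration matrices/out-rates; epoch e = after e merges."""
    nd = demography.n_demes
    base = np.asarray(demography.migration, dtype=float)
    nmerge = len(demography.merges)
    mig_ep = np.zeros((nmerge + 1, nd, nd))
    out_ep = np.zeros((nmerge + 1, nd))
    cur = base.copy()
    inactive = np.zeros(nd, dtype=bool)
    for e in range(nmerge + 1):
        mig_ep[e] = cur
        out_ep[e] = cur.sum(axis=1)
        if e < nmerge:
            _, src, _dst = demography.merges[e]
            inactive[src] = True
            cur = cur.copy()
            cur[src, :] = 0.0
            cur[:, src] = 0.0
    return mig_ep, out_ep


def _kernel_inputs(demography: Demography,
                   population_of_sample: list[str] | None = None):
    pops: list[str] = []
    pop_of_sample: list[int] = []
    deme_of_sample: list[int] = []
    if population_of_sample is None:
        for d, (s, lab) in enumerate(zip(demography.sample_sizes,
                                         demography.labels)):
            if s == 0:
                continue
            pops.append(lab)
            pop_of_sample.extend([len(pops) - 1] * s)
            deme_of_sample.extend([d] * s)
    else:
        idx = 0
        for d, s in enumerate(demography.sample_sizes):
            for _ in range(s):
                lab = population_of_sample[idx]
                if lab not in pops:
                    pops.append(lab)
                pop_of_sample.append(pops.index(lab))
                deme_of_sample.append(d)
                idx += 1
    pop_sizes = np.bincount(pop_of_sample, minlength=len(pops))
    mig_ep, out_ep = _epoch_matrices(demography)
    merges = demography.merges
    return (pops,
            np.asarray(pop_of_sample, dtype=np.int32),
            np.asarray(deme_of_sample, dtype=np.int32),
            pop_sizes.astype(np.int32),
            np.asarray(demography.deme_sizes, dtype=float),
            mig_ep, out_ep,
            np.asarray([m[0] for m in merges], dtype=float),
            np.asarray([m[1] for m in merges], dtype=np.int32),
            np.asarray([m[2] for m in merges], dtype=np.int32))


def _run_kernel(demography: Demography, harvest_pops, n_accepted: int,
                seed: int, max_proposals: int | None,
                population_of_sample=None):
    (pops, pop_of_sample, deme_of_sample, pop_sizes, deme_size,
     mig_ep, out_ep, m_t, m_s, m_d) = _kernel_inputs(
        demography, population_of_sample)
    harvest = np.zeros(len(pops), dtype=bool)
    for p in harvest_pops:
        if p not in pops:
            raise ValueError(f"unknown population {p!r}")
        harvest[pops.index(p)] = True
    if max_proposals is None:
        max_proposals = max(2000 * n_accepted, 200_000)
    res_pop = np.zeros(n_accepted, dtype=np.int32)
    res_class = np.zeros(n_accepted, dtype=np.int8)
    res_w = np.zeros(n_accepted, dtype=float)
    kseed = int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)
    n_acc, n_prop = _island_kernel(
        kseed, n_accepted, max_proposals,
        pop_of_sample, deme_of_sample, pop_sizes,
        deme_size, mig_ep, out_ep, m_t, m_s, m_d,
        harvest, res_pop, res_class, res_w)
    if n_acc < n_accepted:
        raise RuntimeError(
            f"only {n_acc}/{n_accepted} trees accepted within "
            f"{n_prop} proposals (acceptance rate {n_acc / max(n_prop, 1):.3e})")
    return pops, res_pop[:n_acc], res_class[:n_acc], res_w[:n_acc], n_prop


def _weighted_estimate(classes: np.ndarray, weights: np.ndarray,
                       n_prop: int, seed: int) -> ISEstimate:
    kept = classes != CLASS_NEITHER
    w = weights[kept]
    if w.sum() <= 0:
        raise RuntimeError("all simulations discarded (no disrupting events)")
    ra = classes[kept] == CLASS_RA
    w_ra = float(w[ra].sum())
    w_ro = float(w[~ra].sum())
    f = w_ra / (w_ra + w_ro)
    ess = float(w.sum() ** 2 / (w ** 2).sum())
    se = math.sqrt(max(f * (1 - f), 1e-12) / ess)
    return ISEstimate(fraction_ra=f, w_ra=w_ra, w_ro=w_ro,
                      n_accepted=len(classes), n_kept=int(kept.sum()),
                      n_proposals=n_prop, ess=ess, se=se, seed=seed)


def estimate_fraction(demography: Demography, target_pop: str,
                      n_accepted: int = 100_000, seed: int = 0,
                      max_proposals: int | None = None,
                      population_of_sample=None) -> ISEstimate:
    """Importance-sampling estimate of the R_A fraction for one population.

    Simulates structured-coalescent genealogies, keeps those in which
    ``target_pop`` is an outgroup clade, proposes one recombination per
    tree and returns the branch-length-weighted fraction of disrupting
    events ancestral to the clade.
    """
    if n_accepted < 1000:
        raise ValueError("need n_accepted >= 1000")
    _, rp, rc, rw, n_prop = _run_kernel(
        demography, [target_pop], n_accepted, seed, max_proposals,
        population_of_sample)
    return _weighted_estimate(rc, rw, n_prop, seed)


def estimate_fraction_pooled(demography: Demography, clade_size: int,
                             n_accepted: int = 100_000, seed: int = 0,
                             max_proposals: int | None = None) -> ISEstimate:
    """Pooled estimate over all populations of a given sample size.

    Valid when those populations are exchangeable (the symmetric island
    model): any accepted tree whose outgroup population has ``clade_size``
    samples is an equally valid draw for a fixed target after relabeling,
    which raises the acceptance rate by the number of such populations.
    """
    sizes = demography.population_sizes()
    targets = [p for p, s in sizes.items() if s == clade_size]
    if not targets:
        raise ValueError(f"no population of size {clade_size}")
    _, rp, rc, rw, n_prop = _run_kernel(
        demography, targets, n_accepted, seed, max_proposals)
    return _weighted_estimate(rc, rw, n_prop, seed)


def table2(M_values=(0.1, 1.0, 10.0, 100.0), clade_sizes=(3, 2),
           n_accepted: int = 100_000, seed: int = 0,
           samples=(3, 3, 3, 2, 2), include_infinity: bool = True,
           merge_time: float | None = None):
    """R_A fraction estimates for the symmetric 5-island model.

    One row per migration parameter, one column per outgroup clade size;
    the infinite-migration row is computed exactly from the panmictic
    closed form (a single panmictic deme).  Returns a pandas DataFrame
    with matching ``<col>_se`` columns (zero for the exact row).
    """
    import pandas as pd

    n = sum(samples)
    rows = []
    for i, M in enumerate(M_values):
        row = {"M": M}
        for j, k in enumerate(clade_sizes):
            demo = Demography.symmetric_island(d=len(samples), M=M,
                                               samples=samples,
                                               merge_time=merge_time)
            est = estimate_fraction_pooled(
                demo, k, n_accepted=n_accepted,
                seed=int(np.random.SeedSequence([seed, i, j]).generate_state(1)[0]))
            row[f"k={k}"] = est.fraction_ra
            row[f"k={k}_se"] = est.se
        rows.append(row)
    if include_infinity:
        row = {"M": math.inf}
        for k in clade_sizes:
            row[f"k={k}"] = panmictic.fraction_ra(n, k)
            row[f"k={k}_se"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pure-Python conditioned-tree simulator (reference implementation)
# ---------------------------------------------------------------------------

@dataclass
class ConditionedTree:
    """A structured-coalescent genealogy accepted for one outgroup target."""

    times: dict
    parents: dict
    children: dict
    leaf_pops: dict
    demes_at_birth: dict
    n_proposals: int

    @property
    def root(self):
        return max(self.times, key=self.times.get)

    def total_length(self) -> float:
        return sum(self.times[self.parents[x]] - self.times[x]
                   for x in self.parents)


def simulate_conditioned_tree(demography: Demography, target_pop: str,
                              seed: int = 0,
                              max_proposals: int = 1_000_000,
                              population_of_sample=None,
                              rng: np.random.Generator | None = None
                              ) -> ConditionedTree:
    """Rejection-sample one genealogy with ``target_pop`` as outgroup clade.

    Straightforward event-by-event reference implementation used for
    validation; :func:`estimate_fraction` uses a compiled kernel instead.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    (pops, pop_of_sample, deme_of_sample, pop_sizes, deme_size,
     mig_ep, out_ep, m_t, m_s, m_d) = _kernel_inputs(
        demography, population_of_sample)
    if target_pop not in pops:
        raise ValueError(f"unknown population {target_pop!r}")
    tgt = pops.index(target_pop)
    nsam = len(pop_of_sample)
    target_leaves = frozenset(i for i in range(nsam)
                              if pop_of_sample[i] == tgt)
    if len(target_leaves) < 2:
        raise ValueError("target population needs >= 2 samples")
    for prop in range(1, max_proposals + 1):
        times = {i: 0.0 for i in range(nsam)}
        parents: dict = {}
        children: dict = {}
        demes = {i: int(deme_of_sample[i]) for i in range(nsam)}
        birth = dict(demes)
        leafsets = {i: frozenset([i]) for i in range(nsam)}
        active = set(range(nsam))
        t = 0.0
        epoch = 0
        nxt = nsam
        ok = True
        while len(active) > 1:
            per_deme: dict = {}
            for x in active:
                per_deme.setdefault(demes[x], []).append(x)
            coal = sum(len(v) * (len(v) - 1) / 2 / deme_size[d]
                       for d, v in per_deme.items())
            mig = sum(len(v) * out_ep[epoch, d] for d, v in per_deme.items())
            tot = coal + mig
            t_merge = m_t[epoch] if epoch < len(m_t) else math.inf
            dt = rng.exponential(1 / tot) if tot > 0 else math.inf
            if t + dt >= t_merge:
                if not math.isfinite(t_merge):
                    ok = False
                    break
                t = t_merge
                for x in active:
                    if demes[x] == m_s[epoch]:
                        demes[x] = int(m_d[epoch])
                epoch += 1
                continue
            t += dt
            if rng.uniform() * tot < coal:
                ds = [d for d in per_deme if len(per_deme[d]) >= 2]
                wts = np.array([len(per_deme[d]) * (len(per_deme[d]) - 1)
                                / 2 / deme_size[d] for d in ds])
                d = ds[rng.choice(len(ds), p=wts / wts.sum())]
                a, b = rng.choice(per_deme[d], size=2, replace=False)
                w = nxt
                nxt += 1
                times[w] = t
                parents[a] = parents[b] = w
                children[w] = (int(a), int(b))
                leafsets[w] = leafsets[a] | leafsets[b]
                demes[w] = int(d)
                birth[w] = int(d)
                active -= {a, b}
                active.add(w)
                inter = leafsets[w] & target_leaves
                if inter and (leafsets[w] - target_leaves):
                    if inter != target_leaves or len(active) > 1:
                        ok = False
                        break
            else:
                ds = list(per_deme)
                wts = np.array([len(per_deme[d]) * out_ep[epoch, d]
                                for d in ds])
                if wts.sum() <= 0:
                    continue
                d = ds[rng.choice(len(ds), p=wts / wts.sum())]
                x = per_deme[d][rng.integers(len(per_deme[d]))]
                row = mig_ep[epoch, d]
                dest = rng.choice(len(row), p=row / row.sum())
                demes[x] = int(dest)
        if not ok:
            continue
        return ConditionedTree(times=times, parents=parents,
                               children=children,
                               leaf_pops={i: pops[pop_of_sample[i]]
                                          for i in range(nsam)},
                               demes_at_birth=birth, n_proposals=prop)
    raise RuntimeError(
        f"no acceptance within {max_proposals} proposals for {target_pop!r}")


# ---------------------------------------------------------------------------
# perturbation presets
# ---------------------------------------------------------------------------

def perturbation_presets(M: float = 1.0, tau: float = 2.0,
                         samples=(3, 3, 3, 2, 2)) -> dict[str, Demography]:
    """Named deviations from the symmetric island model.

    Families: (A) the outgroup population ``A`` (= pop1) or another
    population ``B`` (= pop2) with a five-fold larger or smaller effective
    size; (B) backward-time migration out of / into ``A`` inflated 5/10/50
    fold (forward-time immigration into / emigration out of ``A``);
    (C) populations joining the ancestral panmictic pool at staggered
    times.  ``tau`` is the base join time in coalescent units; the base
    model has all demes joining the pool at ``tau``.
    """
    d = len(samples)

    def sym(**kw):
        return Demography.symmetric_island(d=d, M=M, samples=samples, **kw)

    base = sym(merge_time=tau)
    out: dict[str, Demography] = {"base": base}
    for name, idx in (("A", 0), ("B", 1)):
        for fac, suffix in ((5.0, "x5"), (0.2, "d5")):
            sizes = [1.0] * d
            sizes[idx] = fac
            out[f"{name}_Ne_{suffix}"] = sym(merge_time=tau,
                                             deme_sizes=tuple(sizes))
    rate = 0.5 * M / (d - 1)
    for fac in (5, 10, 50):
        mig_in = [[rate if i != j else 0.0 for j in range(d)] for i in range(d)]
        mig_out = [[rate if i != j else 0.0 for j in range(d)] for i in range(d)]
        for j in range(1, d):
            mig_in[0][j] *= fac   # forward-time immigration into A
            mig_out[j][0] *= fac  # forward-time emigration out of A
        for which, mig in (("in", mig_in), ("out", mig_out)):
            out[f"A_mig_{which}_x{fac}"] = Demography(
                deme_sizes=(1.0,) * d,
                migration=tuple(tuple(r) for r in mig),
                sample_sizes=tuple(samples),
                labels=base.labels,
                merges=tuple((tau, i, 0) for i in range(1, d)))
    # (C) staggered pool-join times: the named deme joins at 2*tau or tau/2
    for name, idx in (("A", 0), ("B", 1)):
        others = [i for i in range(1, d) if i != idx] if idx != 0 else \
            list(range(2, d))
        pool = 1 if idx == 0 else 0
        late = sorted([(tau, i, pool) for i in others] +
                      [(2 * tau, idx, pool)])
        early = sorted([(tau / 2, idx, pool)] +
                       [(tau, i, pool) for i in others])
        out[f"{name}_old_x2"] = Demography(
            deme_sizes=base.deme_sizes, migration=base.migration,
            sample_sizes=base.sample_sizes, labels=base.labels,
            merges=tuple(late))
        out[f"{name}_young_d2"] = Demography(
            deme_sizes=base.deme_sizes, migration=base.migration,
            sample_sizes=base.sample_sizes, labels=base.labels,
            merges=tuple(early))
    return out
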