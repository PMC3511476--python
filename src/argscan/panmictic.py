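"""Closed-form disruption probabilities under the standard coalescent.

Setting: a sample of ``n`` haplotypes from a single panmictic population,
with a designated set of ``k`` samples forming an *outgroup clade* (one of
the two branches adjacent to the root subtends exactly those samples — the
conditioning event ``O_A``).  A single recombination event is placed on the
tree with intensity rho/2 per lineage per unit of coalescent time; the
recombinant lineage floats up, recoalescing with each surviving lineage at
pair rate 1.  The event is *disrupting* if the regrafted tree no longer has
the clade in outgroup position, and is classified ``R_A`` if the recombinant
lineage is ancestral only to clade members, ``R_O`` if only to non-members.

The model tracks the *level* (number of ancestors of the whole sample) and
the per-level count of clade-ancestral lineages.  Conditional on ``O_A``
these counts form a Markov chain with only within-clade and within-rest
coalescences until the root; level durations are Exp(j(j-1)/2).  Writing
``a_j`` for the clade-ancestral count at level ``j``, the per-level
expectations

    A_j = E[int_0^{T_j} e^{-j r} dr]     = 2 / (j (j + 1))
    B_j = E[int_0^{T_j} (1 - e^{-j r}) dr] = 4 / (j (j^2 - 1))
    S_l = E[e^{-l T_l}] = (l - 1) / (l + 1)
    C_i = E[1 - e^{-i T_i}] = 2 / (i + 1)

combine with the purely topological disruption rules:

* ``R_A`` (recombination on a clade lineage): disrupting unless the regraft
  partner is clade-ancestral, or the pruned lineage carries the *whole*
  clade and the partner is the complete non-clade stem or the beyond-root
  stem (in those cases the clade is still an outgroup after the swap);
* ``R_O`` (recombination on a non-clade lineage): disrupting iff the
  partner is clade-ancestral, unless the pruned lineage carries the whole
  non-clade side and the partner is the clade stem.

The probability that more than one recombination occurs is O(rho^2) and is
ignored; the common factor rho/2 and the probability of the conditioning
event cancel in the ``R_A`` fraction, which is the quantity consumed
downstream and tabulated over ``(n, k)`` grids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PanmicticParams:
    n: int
    k: int
    rho: float = 1.0

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("need total sample size n >= 3")
        if not (2 <= self.k <= self.n - 1):
            raise ValueError("need outgroup clade size 2 <= k <= n-1")
        if not self.rho > 0:
            raise ValueError("rho must be positive")


@dataclass(frozen=True)
class DisruptionProbabilities:
    """Unnormalized P(R_A & disrupting | O_A), P(R_O & ...), and their ratio."""

    p_ra: float
    p_ro: float

    @property
    def fraction_ra(self) -> float:
        return self.p_ra / (self.p_ra + self.p_ro)


def _per_level_constants(n: int):
    A = np.zeros(n + 1)
    B = np.zeros(n + 1)
    C = np.zeros(n + 1)
    PS = np.ones(n + 1)  # PS[t] = prod_{l=2..t} E[e^{-l T_l}]
    for j in range(2, n + 1):
        A[j] = 2.0 / (j * (j + 1))
        B[j] = 4.0 / (j * (j * j - 1))
        C[j] = 2.0 / (j + 1)
        PS[j] = PS[j - 1] * (j - 1) / (j + 1)
    return A, B, C, PS


def _transition_matrices(n: int, k: int) -> dict[int, np.ndarray]:
    """T[l][u, u'] = P(level l -> l-1 moves clade count u -> u'), pure merges."""
    T = {}
    for l in range(3, n + 1):
        M = np.zeros((k + 1, k + 1))
        tot = l * (l - 1) / 2.0
        for u in range(1, min(k, l - 1) + 1):
            b = l - u
            if u >= 2:
                M[u, u - 1] = u * (u - 1) / 2.0 / tot
            if b >= 2:
                M[u, u] = b * (b - 1) / 2.0 / tot
        T[l] = M
    return T


def disruption_probabilities(params: PanmicticParams) -> DisruptionProbabilities:
    """Exact single-recombination disruption probabilities given ``O_A``.

    Evaluated by forward-backward dynamic programming over the
    clade-ancestral lineage count per level, O(n^2 k) time, accurate in
    double precision across the full tabulated range (n up to 100).
    """
    n, k = params.n, params.k
    A, B, C, PS = _per_level_constants(n)
    T = _transition_matrices(n, k)
    F = {n: np.zeros(k + 1)}
    F[n][k] = 1.0
    for l in range(n, 2, -1):
        F[l - 1] = F[l] @ T[l]
    G = {2: np.zeros(k + 1)}
    G[2][1] = 1.0
    for l in range(3, n + 1):
        G[l] = T[l] @ G[l - 1]
    Z = F[2][1]  # = P(O_A) for the specified k-subset
    if Z <= 0:
        raise ValueError("conditioning event has probability zero")
    u_arr = np.arange(k + 1, dtype=float)

    p_ra = 0.0
    p_ro = 0.0
    for j in range(2, n + 1):
        marg = F[j] * G[j] / Z
        for u in range(1, min(k, j - 1) + 1):
            b = j - u
            # recoalescence within level j
            if not (u == 1 and j == 2):
                p_ra += marg[u] * u * B[j] * (b / j)
            d = u - (1 if (b == 1 and u == 1) else 0)
            p_ro += marg[u] * b * B[j] * (d / j)
            # recoalescence beyond the root (with the grand-MRCA stem)
            if u >= 2:
                p_ra += marg[u] * u * A[j] * PS[j - 1]
            if b >= 2:
                p_ro += marg[u] * b * A[j] * PS[j - 1]
        if j < 3:
            continue
        # recoalescence at levels 2 <= i < j: propagate the level-j state
        # down, accumulating partner terms; separate vectors carry the
        # whole-clade (a_j = 1) and whole-rest (b_j = 1) exception mass.
        phi_ra = F[j] * u_arr
        phi_ra1 = np.zeros(k + 1)
        phi_ra1[1] = F[j][1]
        phi_ro = F[j] * (j - u_arr)
        phi_ro[0] = 0.0
        phi_rob1 = np.zeros(k + 1)
        if j - 1 <= k:
            phi_rob1[j - 1] = F[j][j - 1]
        acc_ra = acc_ro = 0.0
        for i in range(j - 1, 1, -1):
            phi_ra = phi_ra @ T[i + 1]
            phi_ra1 = phi_ra1 @ T[i + 1]
            phi_ro = phi_ro @ T[i + 1]
            phi_rob1 = phi_rob1 @ T[i + 1]
            w = G[i] * (C[i] / PS[i])
            acc_ra += float(np.sum(phi_ra * w * (i - u_arr) / i))
            if i == 2:
                acc_ra -= float(np.sum(phi_ra1 * w * (i - u_arr) / i))
            acc_ro += float(np.sum(phi_ro * w * u_arr / i))
            acc_ro -= phi_rob1[1] * w[1] / i
        p_ra += A[j] * PS[j - 1] * acc_ra / Z
        p_ro += A[j] * PS[j - 1] * acc_ro / Z
    scale = params.rho / 2.0
    return DisruptionProbabilities(p_ra=scale * p_ra, p_ro=scale * p_ro)


def fraction_ra(n: int, k: int) -> float:
    """Convenience: R_A fraction of disrupting events for (n, k)."""
    return disruption_probabilities(PanmicticParams(n=n, k=k)).fraction_ra


def _fraction_ra_enumerated(n: int, k: int) -> float:
    """Same quantity by brute-force enumeration of level profiles.

    Exponential in k; used as an internal cross-check of the DP at small n.
    """
    A, B, C, PS = _per_level_constants(n)
    p_ra = p_ro = Z = 0.0
    for clade_levels in combinations(range(3, n + 1), k - 1):
        a = {}
        cur = k
        w = 1.0
        ok = True
        for l in range(n, 1, -1):
            a[l] = cur
            if l == 2:
                break
            b = l - cur
            tot = l * (l - 1) / 2.0
            if l in clade_levels:
                if cur < 2:
                    ok = False
                    break
                w *= cur * (cur - 1) / 2.0 / tot
                cur -= 1
            else:
                if b < 2:
                    ok = False
                    break
                w *= b * (b - 1) / 2.0 / tot
        if not ok or a.get(2) != 1:
            continue
        Z += w
        fra = fro = 0.0
        for j in range(2, n + 1):
            aj, bj = a[j], j - a[j]
            if aj >= 1:
                if not (aj == 1 and j == 2):
                    fra += aj * B[j] * (bj / j)
                for i in range(2, j):
                    if aj == 1 and i == 2:
                        continue
                    fra += aj * A[j] * (PS[j - 1] / PS[i]) * C[i] * ((i - a[i]) / i)
                if aj >= 2:
                    fra += aj * A[j] * PS[j - 1]
            if bj >= 1:
                d = a[j] - (1 if (bj == 1 and a[j] == 1) else 0)
                fro += bj * B[j] * (d / j)
                for i in range(2, j):
                    d = a[i] - (1 if (bj == 1 and a[i] == 1) else 0)
                    fro += bj * A[j] * (PS[j - 1] / PS[i]) * C[i] * (d / i)
                if bj >= 2:
                    fro += bj * A[j] * PS[j - 1]
        p_ra += w * fra
        p_ro += w * fro
    return p_ra / (p_ra + p_ro)


def table1(n_values=None, k_values=(2, 3)) -> pd.DataFrame:
    """Grid of R_A fractions over (n, k), one row per n."""
    if n_values is None:
        n_values = list(range(3, 16)) + [20, 100]
    rows = []
    for n in n_values:
        row = {"n": n}
        for k in k_values:
            row[f"k={k}"] = fraction_ra(n, k) if 2 <= k <= n - 1 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# outgroup/clade probabilities
# ---------------------------------------------------------------------------

def prob_clade(n: int, k: int) -> float:
    """P(a specified set of k samples forms a clade) in a coalescent tree.

    Dynamic program over (clade lineages, other lineages): the clade forms
    iff its ancestors only merge among themselves until they reach a single
    lineage; within-group pairs coalesce at rate a(a-1)/2 against the total
    pair rate.
    """
    if not (1 <= k <= n):
        raise ValueError("need 1 <= k <= n")
    if k in (1, n):
        return 1.0
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(a: int, b: int) -> float:
        if a == 1:
            return 1.0
        tot = (a + b) * (a + b - 1) / 2.0
        p = (a * (a - 1) / 2.0 / tot) * rec(a - 1, b)
        if b >= 2:
            p += (b * (b - 1) / 2.0 / tot) * rec(a, b - 1)
        return p

    return rec(k, n - k)


def prob_outgroup(n: int, k: int) -> float:
    """P(O_A): a specified k-set is an outgroup clade (both sides pure)."""
    params = PanmicticParams(n=n, k=k)
    T = _transition_matrices(n, k)
    F = np.zeros(k + 1)
    F[k] = 1.0
    for l in range(n, 2, -1):
        F = F @ T[l]
    return float(F[1])


def prob_outgroup_given_clade(n: int, k: int) -> float:
    """P(the clade is an outgroup | the k samples form a clade)."""
    if not (2 <= k <= n - 1):
        raise ValueError("need 2 <= k <= n-1")
    return prob_outgroup(n, k) / prob_clade(n, k)


def prob_specific_outgroup(n: int) -> tuple[float, float]:
    """For ``n`` exchangeable lineages: (P(a prespecified lineage is an
    outgroup), P(no lineage is an outgroup)).

    A specific lineage is an outgroup iff it joins the tree only at the
    final coalescence: it escapes the merge at level ``l`` with probability
    (l-2)/l, giving 2/(n(n-1)); the per-lineage events are mutually
    exclusive for n >= 3, so P(none) = 1 - 2/(n-1).
    """
    if n < 3:
        raise ValueError("need n >= 3")
    p_one = 2.0 / (n * (n - 1))
    return p_one, 1.0 - n * p_one


def enumerate_specific_outgroup(n: int) -> tuple[float, float]:
    """Same two probabilities by exhaustive enumeration of merge histories.

    Independent check of :func:`prob_specific_outgroup`; feasible for
    n <= 7 or so.
    """
    from fractions import Fraction

    p_one = Fraction(0)
    p_none = Fraction(0)

    def rec(groups: tuple[frozenset, ...], w: Fraction):
        nonlocal p_one, p_none
        if len(groups) == 2:
            singles = [g for g in groups if len(g) == 1]
            if any(g == frozenset([0]) for g in singles):
                p_one += w
            if not singles:
                p_none += w
            return
        pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
        for i, j in pairs:
            merged = tuple(g for t, g in enumerate(groups) if t not in (i, j)) \
                + (groups[i] | groups[j],)
            rec(merged, w / len(pairs))

    rec(tuple(frozenset([i]) for i in range(n)), Fraction(1))
    return float(p_one), float(p_none)


# ---------------------------------------------------------------------------
# Monte-Carlo oracle: brute-force simulation with explicit tree surgery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleEstimate:
    fraction_ra: float
    se: float
    p_ra_hat: float
    p_ro_hat: float
    n_accepted: int
    n_kept: int
    m_samples: tuple[int, ...] = ()
    #: per accepted tree, the levels (pre-merge lineage counts of the whole
    #: sample) at which the clade's internal coalescences happened; given
    #: outgroup status this configuration is uniform over its valid range,
    #: and for clade size 2 its single entry minus one (= m) is uniform
    clade_level_samples: tuple[tuple[int, ...], ...] = ()

    @property
    def fraction_ra_interval(self) -> tuple[float, float]:
        return (self.fraction_ra - 3 * self.se, self.fraction_ra + 3 * self.se)


def _simulate_kingman(n: int, rng: np.random.Generator):
    """One standard coalescent tree: times, parents, children, merge order."""
    n_nodes = 2 * n - 1
    time = np.zeros(n_nodes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    children = np.full((n_nodes, 2), -1, dtype=np.int64)
    active = list(range(n))
    t = 0.0
    nxt = n
    merge_order = []
    while len(active) > 1:
        j = len(active)
        t += rng.exponential(2.0 / (j * (j - 1)))
        i1, i2 = rng.choice(j, size=2, replace=False)
        a, b = active[i1], active[i2]
        time[nxt] = t
        parent[a] = parent[b] = nxt
        children[nxt] = (a, b)
        merge_order.append((a, b, nxt))
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return time, parent, children, merge_order


def _leafset(children, node, n) -> frozenset[int]:
    out = set()
    stack = [int(node)]
    while stack:
        x = stack.pop()
        if x < n:
            out.add(x)
        else:
            stack.extend(int(c) for c in children[x])
    return frozenset(out)


def _is_outgroup_split(children_map, root, n, target: frozenset[int]) -> bool:
    kids = children_map[root]
    for c in kids:
        out = set()
        stack = [c]
        while stack:
            x = stack.pop()
            if x < n:
                out.add(x)
            else:
                stack.extend(children_map[x])
        if frozenset(out) == target:
            return True
    return False


def mc_oracle(params: PanmicticParams, reps: int = 10_000,
              seed: int | None = None,
              collect_m: bool = False,
              max_iter: int | None = None) -> OracleEstimate:
    """Brute-force estimate of the disruption probabilities.

    Rejection-samples coalescent trees until the target samples are an
    outgroup clade (using exchangeability: any size-``k`` root child is a
    valid draw after relabeling, so acceptance only requires the root split
    to have a side of size ``k``); places one recombination uniformly by
    branch length; lets the recombinant lineage recoalesce at pair rate 1
    with the surviving lineages (continuing beyond the root with the grand
    MRCA stem); performs the subtree regraft explicitly and tests outgroup
    status of the new tree from its leaf sets.  Trees are weighted by total
    branch length.  Entirely independent of the closed-form case analysis.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000 for a stable estimate")
    n, k = params.n, params.k
    rng = np.random.default_rng(seed)
    if max_iter is None:
        max_iter = 5000 * reps
    accepted = 0
    it = 0
    w_ra = w_ro = 0.0
    w_kept = w_kept_sq = 0.0
    n_kept = 0
    w_all = 0.0
    m_samples: list[int] = []
    level_samples: list[tuple[int, ...]] = []
    while accepted < reps:
        it += 1
        if it > max_iter:
            raise RuntimeError(
                f"no acceptance within {max_iter} iterations "
                f"(acceptance rate ~{accepted / it:.2e})")
        time, parent, children, merge_order = _simulate_kingman(n, rng)
        root = 2 * n - 2
        sides = [int(c) for c in children[root]]
        targets = [c for c in sides if len(_leafset(children, c, n)) == k]
        for clade_root in targets:
            accepted += 1
            target = _leafset(children, clade_root, n)
            if collect_m:
                e_star = next(i for i, (_, _, w) in enumerate(merge_order)
                              if w == clade_root)
                m_samples.append(n - (e_star + 1))
                internal = {x for x in range(n, 2 * n - 1)
                            if _leafset(children, x, n) <= target}
                levels = tuple(sorted(
                    n - e for e, (_, _, w) in enumerate(merge_order)
                    if w in internal))
                level_samples.append(levels)
            # --- place one recombination uniformly on the branches
            lens = np.array([time[parent[x]] - time[x]
                             for x in range(2 * n - 2)])
            L = float(lens.sum())
            w_all += L
            b = int(rng.choice(2 * n - 2, p=lens / L))
            t_r = time[b] + rng.uniform() * lens[b]
            # --- recoalesce: piecewise-constant rate = #existing lineages
            node_times = sorted((float(time[x]), int(x))
                                for x in range(n, 2 * n - 1))
            t = t_r
            t_c = None
            while True:
                existing = [x for x in range(2 * n - 1)
                            if time[x] <= t and (parent[x] == -1
                                                 or time[parent[x]] > t)]
                rate = len(existing)
                nxt_change = next((tt for tt, _ in node_times if tt > t),
                                  math.inf)
                dt = rng.exponential(1.0 / rate)
                if t + dt < nxt_change:
                    t_c = t + dt
                    partner = int(existing[rng.integers(rate)])
                    break
                t = nxt_change
            # --- explicit regraft and outgroup test
            if partner == b:
                continue  # bubble: tree unchanged, not disrupting
            cmap = {int(x): [int(c) for c in children[x]]
                    for x in range(n, 2 * n - 1)}
            pmap = {int(x): int(parent[x]) for x in range(2 * n - 1)}
            pb = pmap[b]
            sib = [c for c in cmap[pb] if c != b][0]
            gp = pmap[pb]
            # contract pb
            del cmap[pb]
            if gp == -1:
                new_root = sib
                pmap[sib] = -1
            else:
                cmap[gp] = [sib if c == pb else c for c in cmap[gp]]
                pmap[sib] = gp
                new_root = root if root != pb else sib
            if partner == pb:
                partner = sib
            X = 2 * n - 1  # regraft node
            if pmap[partner] == -1:
                # join with the root stem: X becomes the new root
                cmap[X] = [partner, b]
                pmap[partner] = X
                pmap[b] = X
                pmap[X] = -1
                new_root = X
            else:
                gpp = pmap[partner]
                cmap[gpp] = [X if c == partner else c for c in cmap[gpp]]
                cmap[X] = [partner, b]
                pmap[partner] = X
                pmap[b] = X
                pmap[X] = gpp
            still = _is_outgroup_split(cmap, new_root, n, target)
            if still:
                continue  # not disrupting
            desc = _leafset(children, b, n)
            n_kept += 1
            w_kept += L
            w_kept_sq += L * L
            if desc <= target:
                w_ra += L
            elif not (desc & target):
                w_ro += L
            else:  # pragma: no cover - impossible on conditioned true trees
                raise AssertionError("mixed recombinant lineage under O_A")
    if w_ra + w_ro == 0:
        raise RuntimeError("all simulations discarded")
    f = w_ra / (w_ra + w_ro)
    ess = w_kept * w_kept / w_kept_sq if w_kept_sq > 0 else 0.0
    se = math.sqrt(f * (1 - f) / ess) if ess > 0 else math.inf
    return OracleEstimate(
        fraction_ra=f, se=se,
        p_ra_hat=w_ra / w_all, p_ro_hat=w_ro / w_all,
        n_accepted=accepted, n_kept=n_kept,
        m_samples=tuple(m_samples),
        clade_level_samples=tuple(level_samples))


def sample_m_given_outgroup(n: int, k: int, reps: int,
                            seed: int | None = None) -> np.ndarray:
    """Draws of m (lineages remaining at the clade MRCA) given outgroup status."""
    est = mc_oracle(PanmicticParams(n=n, k=k), reps=max(reps, 1000),
                    seed=seed, collect_m=True)
    return np.asarray(est.m_samples[:reps])
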