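"""Goldman-Yang style codon-model maximum likelihood (M0 and two-ratio).

The model: a reversible 61-state Markov process on sense codons where only
single-nucleotide codon changes have positive rate,

    q_ij = pi_j * kappa^[transition] * omega^[non-synonymous],

with F3x4 codon frequencies estimated from the data and the generator
scaled so the expected number of substitutions per codon per unit branch
length is one.  A single omega across the tree is the one-ratio (M0)
model; the two-ratio model gives a chosen branch class its own omega and
is compared to M0 by a chi-square(1) likelihood-ratio test.

Felsenstein pruning with codon-pattern compression and an eigendecomposed
symmetrized generator keeps a four-taxon, 400-codon fit well under a
second, which the calibration simulations rely on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from Bio import Phylo
from scipy import optimize, stats

from ._codons import (
    NUCS,
    SENSE_CODONS,
    SENSE_INDEX,
    STOP_CODONS,
    is_synonymous,
    is_transition,
    f3x4_frequencies,
)
from .counting import CodonAlignment

__all__ = ["CodonModelFit", "m0_fit", "two_ratio_lrt", "simulate_codons"]

N_STATES = 61


def _change_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean 61x61 masks: single-step, transition, synonymous."""
    single = np.zeros((N_STATES, N_STATES), dtype=bool)
    transit = np.zeros_like(single)
    synon = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            p = diffs[0]
            transit[i, j] = is_transition(ci[p], cj[p])
            synon[i, j] = is_synonymous(ci, cj)
    return single, transit, synon

_SINGLE, _TS, _SYN = _change_tables()


def _generator(pi: np.ndarray, kappa: float, omega: float) -> tuple[np.ndarray, float, float]:
    """Scaled GY94 generator plus its synonymous/non-synonymous flux split.

    Returns ``(Q, rho_syn, rho_nonsyn)`` where Q has unit mean rate and
    rho_syn + rho_nonsyn = 1 are the proportions of substitutions that are
    synonymous / non-synonymous at stationarity.
    """
    rate = np.where(_SINGLE, pi[None, :], 0.0)
    rate = np.where(_TS, rate * kappa, rate)
    rate = np.where(_SYN, rate, np.where(_SINGLE, rate * omega, 0.0))
    np.fill_diagonal(rate, 0.0)
    flux = pi[:, None] * rate
    total = flux.sum()
    syn_flux = flux[_SYN & _SINGLE].sum()
    Q = rate / total
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, syn_flux / total, 1.0 - syn_flux / total


class _Propagator:
    """Eigendecomposition of a reversible generator for cheap P(t)."""

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        S = (S + S.T) / 2  # enforce symmetry against round-off
        w, V = np.linalg.eigh(S)
        self._w = w
        self._left = V / sq[:, None] * 1.0
        self._right = (V * sq[:, None]).T

    def P(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self._w * t)) @ self._right
        np.clip(P, 1e-300, None, out=P)
        return P


@dataclass
class CodonModelFit:
    """Result of a codon-model ML fit."""

    model: str  # "one-ratio" | "two-ratio"
    omega: float  # background omega
    omega_fg: float | None  # foreground omega (two-ratio only)
    kappa: float
    lnL: float
    tree_length: float  # expected substitutions per codon, summed over branches
    dS: float  # per synonymous site, tree-averaged
    dN: float  # per non-synonymous site, tree-averaged
    branch_lengths: dict
    n_codons: int
    converged: bool
    flags: list


class _TreeLikelihood:
    """Pruning likelihood of a codon alignment on a fixed topology."""

    def __init__(self, aln: CodonAlignment, newick: str, foreground: set | None = None):
        cols = aln.complete_deletion_columns()
        if not cols:
            raise ValueError("no gap/ambiguity-free codon columns")
        codon_idx = np.array(
            [[SENSE_INDEX[s[3 * j : 3 * j + 3]] for j in cols] for s in aln.sequences]
        )
        # pattern compression
        patterns, inverse, counts = np.unique(
            codon_idx.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (npat, ntaxa)
        self.weights = counts.astype(float)
        self.n_codons = len(cols)
        self.pi = f3x4_frequencies(codon_idx)
        self.name_to_row = {n: i for i, n in enumerate(aln.names)}

        tree = Phylo.read(io.StringIO(newick), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        if leaves != set(aln.names):
            raise ValueError(
                f"tree leaves {sorted(leaves)} do not match alignment names {sorted(aln.names)}"
            )
        # flatten into (node, parent) lists; branches indexed per non-root clade
        self.branches = []  # (clade, is_foreground)
        self.children = {}
        fg = foreground or set()

        def walk(clade):
            self.children[id(clade)] = list(clade.clades)
            for child in clade.clades:
                is_fg = child.is_terminal() and child.name in fg
                self.branches.append((child, is_fg))
                walk(child)

        self.root = tree.root
        walk(self.root)
        self.n_branches = len(self.branches)
        unknown = fg - leaves
        if unknown:
            raise ValueError(f"foreground names not in tree: {sorted(unknown)}")

    def log_likelihood(self, branch_lengths: np.ndarray, kappa: float,
                       omega_bg: float, omega_fg: float | None = None) -> float:
        Q_bg, _, _ = _generator(self.pi, kappa, omega_bg)
        prop_bg = _Propagator(Q_bg, self.pi)
        prop_fg = None
        if omega_fg is not None:
            Q_fg, _, _ = _generator(self.pi, kappa, omega_fg)
            prop_fg = _Propagator(Q_fg, self.pi)
        P_of = {}
        for (clade, is_fg), t in zip(self.branches, branch_lengths):
            prop = prop_fg if (is_fg and prop_fg is not None) else prop_bg
            P_of[id(clade)] = prop.P(t)

        npat = self.patterns.shape[0]

        def partial(clade) -> np.ndarray:
            out = np.ones((npat, N_STATES))
            for child in self.children[id(clade)]:
                P = P_of[id(child)]
                if child.is_terminal():
                    obs = self.patterns[:, self.name_to_row[child.name]]
                    out *= P[:, obs].T
                else:
                    out *= partial(child) @ P.T
            return out

        L = partial(self.root) @ self.pi
        return float(self.weights @ np.log(L))


def _parse_or_default_tree(aln: CodonAlignment, tree: str | None) -> str:
    if tree is not None:
        return tree
    if aln.tree is not None:
        return aln.tree
    names = aln.names
    if len(names) < 3:
        raise ValueError("need >= 3 sequences for a tree-based fit")
    if len(names) == 3:
        return "(" + ",".join(f"{n}:0.05" for n in names) + ");"
    inner = f"({names[0]}:0.05,{names[1]}:0.05):0.02"
    rest = ",".join(f"{n}:0.05" for n in names[2:])
    return f"({inner},{rest});"


_OMEGA_STARTS = (0.1, 0.5, 1.5)


def _fit(engine: _TreeLikelihood, two_ratio: bool, tol: float = 1e-8):
    nb = engine.n_branches
    n_omega = 2 if two_ratio else 1

    def unpack(x):
        bl = np.exp(x[:nb])
        kappa = np.exp(x[nb])
        om_bg = np.exp(x[nb + 1])
        om_fg = np.exp(x[nb + 2]) if two_ratio else None
        return bl, kappa, om_bg, om_fg

    def negll(x):
        bl, kappa, om_bg, om_fg = unpack(x)
        try:
            return -engine.log_likelihood(bl, kappa, om_bg, om_fg)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12

    bounds = [(np.log(1e-6), np.log(20.0))] * nb
    bounds += [(np.log(0.05), np.log(50.0))]  # kappa
    bounds += [(np.log(1e-5), np.log(50.0))] * n_omega

    best = None
    trace = []
    for omega0 in _OMEGA_STARTS:
        x0 = np.concatenate(
            [np.log(np.full(nb, 0.05)), [np.log(2.0)], np.log(np.full(n_omega, omega0))]
        )
        res = optimize.minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "maxiter": 500},
        )
        trace.append((omega0, -res.fun, res.success))
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"codon-model optimization failed; starts tried: {trace}")
    return best, trace


def _fit_to_result(engine: _TreeLikelihood, res, two_ratio: bool, model: str) -> CodonModelFit:
    nb = engine.n_branches
    bl = np.exp(res.x[:nb])
    kappa = float(np.exp(res.x[nb]))
    omega = float(np.exp(res.x[nb + 1]))
    omega_fg = float(np.exp(res.x[nb + 2])) if two_ratio else None
    flags = []
    if omega < 1e-4:
        flags.append("omega at lower boundary (no non-synonymous signal)")
    T = float(bl.sum())
    # per-site dS/dN following the codeml convention: substitution flux split
    # under the fitted model, site counts from the neutral (omega=1) flux
    _, rho_s, rho_n = _generator(engine.pi, kappa, omega)
    _, rho_s1, rho_n1 = _generator(engine.pi, kappa, 1.0)
    dS = T * rho_s / (3 * rho_s1) if rho_s1 > 0 else float("nan")
    dN = T * rho_n / (3 * rho_n1) if rho_n1 > 0 else float("nan")
    names = []
    for i, (clade, _) in enumerate(engine.branches):
        names.append(clade.name if clade.name else f"internal-{i}")
    return CodonModelFit(
        model=model,
        omega=omega,
        omega_fg=omega_fg,
        kappa=kappa,
        lnL=float(-res.fun),
        tree_length=T,
        dS=float(dS),
        dN=float(dN),
        branch_lengths=dict(zip(names, bl.tolist())),
        n_codons=engine.n_codons,
        converged=bool(res.success),
        flags=flags,
    )


def m0_fit(aln: CodonAlignment, tree: str | None = None) -> CodonModelFit:
    """One-ratio (M0) codon-model fit: a single omega and kappa over the
    tree, branch lengths free, F3x4 frequencies from the data.

    Optimization runs L-BFGS-B from three omega starting points (0.1, 0.5,
    1.5) and keeps the best; non-convergence of all starts raises with the
    start trace.  A fit pinned at the omega lower bound (alignment with only
    synonymous variation) is flagged, not an error.
    """
    engine = _TreeLikelihood(aln, _parse_or_default_tree(aln, tree))
    res, _ = _fit(engine, two_ratio=False)
    return _fit_to_result(engine, res, two_ratio=False, model="one-ratio")


def two_ratio_lrt(
    aln: CodonAlignment, tree: str | None, foreground: set | list
) -> tuple[CodonModelFit, CodonModelFit, float, float]:
    """Two-ratio vs one-ratio likelihood-ratio test.

    ``foreground`` names the alleles (tree leaves) whose terminal branches
    get their own omega — here the multi-copy allele(s) versus the
    single-copy alleles.  Returns ``(fit0, fit1, statistic, p)`` with
    statistic = 2(lnL1 - lnL0) ~ chi-square(1) under the null.
    """
    newick = _parse_or_default_tree(aln, tree)
    engine0 = _TreeLikelihood(aln, newick)
    engine1 = _TreeLikelihood(aln, newick, foreground=set(foreground))
    res0, _ = _fit(engine0, two_ratio=False)
    res1, _ = _fit(engine1, two_ratio=True)
    fit0 = _fit_to_result(engine0, res0, two_ratio=False, model="one-ratio")
    fit1 = _fit_to_result(engine1, res1, two_ratio=True, model="two-ratio")
    if fit1.lnL < fit0.lnL:
        # nested models: re-polish the alternative from the null's optimum
        x0 = np.concatenate([res0.x, [res0.x[-1]]])
        nb = engine1.n_branches
        bounds = [(np.log(1e-6), np.log(20.0))] * nb
        bounds += [(np.log(0.05), np.log(50.0)), (np.log(1e-5), np.log(50.0)),
                   (np.log(1e-5), np.log(50.0))]
        res1b = optimize.minimize(
            lambda x: -engine1.log_likelihood(
                np.exp(x[:nb]), np.exp(x[nb]), np.exp(x[nb + 1]), np.exp(x[nb + 2])
            ),
            x0, method="L-BFGS-B", bounds=bounds, options={"ftol": 1e-8, "maxiter": 500},
        )
        if -res1b.fun > fit1.lnL:
            fit1 = _fit_to_result(engine1, res1b, two_ratio=True, model="two-ratio")
    stat = max(0.0, 2.0 * (fit1.lnL - fit0.lnL))
    p = float(stats.chi2.sf(stat, df=1))
    return fit0, fit1, stat, p


def simulate_codons(
    tree: str,
    omega: float,
    kappa: float,
    length: int,
    seed: int,
    pi: np.ndarray | None = None,
    locus: str = "sim",
    foreground: set | None = None,
    omega_fg: float | None = None,
) -> CodonAlignment:
    """Evolve ``length`` codons along ``tree`` under the GY94/F3x4 process.

    Branch lengths in the newick are expected substitutions per codon.  The
    root sequence is drawn from the stationary distribution ``pi`` (uniform
    over sense codons by default); stop codons never occur.  Naming leaves
    in ``foreground`` evolves their terminal branches under ``omega_fg``
    instead of ``omega`` (the two-ratio generating process).
    """
    if omega < 0 or kappa <= 0:
        raise ValueError("omega must be >= 0 and kappa > 0")
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = np.full(N_STATES, 1.0 / N_STATES) if pi is None else np.asarray(pi, float)
    pi = pi / pi.sum()
    Q, _, _ = _generator(pi, kappa, max(omega, 1e-12))
    prop = _Propagator(Q, pi)
    prop_fg = None
    if foreground and omega_fg is not None:
        Q_fg, _, _ = _generator(pi, kappa, max(omega_fg, 1e-12))
        prop_fg = _Propagator(Q_fg, pi)
    fg = foreground or set()
    t = Phylo.read(io.StringIO(tree), "newick")
    root_states = rng.choice(N_STATES, size=length, p=pi)
    seqs: dict[str, np.ndarray] = {}

    def walk(clade, states):
        for child in clade.clades:
            bl = child.branch_length
            if bl is None:
                raise ValueError("tree must carry branch lengths")
            use_fg = prop_fg is not None and child.is_terminal() and child.name in fg
            if bl == 0:
                child_states = states.copy()
            else:
                P = (prop_fg if use_fg else prop).P(bl)
                P = P / P.sum(axis=1, keepdims=True)
                child_states = np.array(
                    [rng.choice(N_STATES, p=P[s]) for s in states]
                )
            if child.is_terminal():
                seqs[child.name] = child_states
            else:
                walk(child, child_states)

    walk(t.root, root_states)
    names = sorted(seqs)
    return CodonAlignment(
        locus=locus,
        names=names,
        sequences=["".join(SENSE_CODONS[s] for s in seqs[n]) for n in names],
        tree=tree,
    )
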