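"""Nucleotide sequence simulation on genealogies.

Substitution models are materialized as constrained GTR rate matrices:
HKY85 (one transition/transversion ratio kappa) and TIM1 (exchangeability
pattern 012230: AC=GT, AT=CG, with AG and CT free).  Among-site rate
heterogeneity uses the discrete-gamma approximation with equiprobable
categories, each site carrying the mean rate of its category.

Mutations are placed on branches by uniformization: virtual events occur
as a Poisson process at the dominating rate ``mu * r_s * qmax`` per site
(``qmax`` the largest total leaving rate of the generator), and each
event applies the jump kernel ``I + Q/qmax``.  This samples the exact
continuous-time Markov chain while touching only the handful of sites
that actually mutate, so a 257-taxon, kilobase-scale replicate costs
milliseconds.  The root sequence is drawn from the stationary base
frequencies, which the chain preserves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .coalescent import Genealogy
from .scenarios import InvalidParameterError

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
# exchangeability index order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class InvalidModelError(ValueError):
    """Substitution model parameters outside their valid domain."""


@dataclass(frozen=True)
class SubstitutionModel:
    """A scaled GTR-family generator with optional gamma rate variation.

    ``rate_matrix`` is scaled so the expected substitution rate at
    stationarity is 1; branch lengths are then measured in expected
    substitutions per site per unit of ``mu * t``.
    """

    family: str
    freqs: np.ndarray
    exchangeabilities: np.ndarray
    alpha: float | None
    ncat: int
    rate_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        s = np.asarray(self.exchangeabilities, dtype=float)
        if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-8:
            raise InvalidModelError("freqs must be a 4-vector summing to 1")
        if s.shape != (6,) or np.any(s <= 0):
            raise InvalidModelError("exchangeabilities must be 6 positive rates")
        if self.alpha is not None and self.alpha <= 0:
            raise InvalidModelError("gamma shape alpha must be > 0")
        if self.ncat < 1:
            raise InvalidModelError("ncat must be >= 1")
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(s, _PAIRS):
            Q[i, j] = r * f[j]
            Q[j, i] = r * f[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mean_rate = -np.dot(f, np.diag(Q))
        if mean_rate <= 0:
            raise InvalidModelError("degenerate rate matrix")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "exchangeabilities", s)
        object.__setattr__(self, "rate_matrix", Q / mean_rate)


def build_substitution_model(
    family: str,
    kappa: float | None = None,
    rates: tuple[float, float, float, float] | None = None,
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    alpha: float | None = None,
    ncat: int = 4,
) -> SubstitutionModel:
    """Build an HKY or TIM1 model as a constrained GTR.

    HKY takes ``kappa`` (transition/transversion rate ratio); with
    kappa = 1 and uniform frequencies it reduces to Jukes-Cantor.  TIM1
    takes ``rates = (a, b, c, d)`` mapped to the 012230 pattern
    (AC=GT=a, AG=b, AT=CG=c, CT=d).
    """
    fam = family.upper()
    if fam == "HKY":
        if kappa is None:
            kappa = 1.0
        if kappa <= 0:
            raise InvalidModelError("kappa must be > 0")
        s = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
    elif fam == "TIM1":
        if rates is None:
            rates = (1.0, 2.0, 1.0, 2.0)
        a, b, c, d = rates
        s = np.array([a, b, c, c, d, a])
    else:
        raise InvalidModelError(f"unknown model family {family!r}")
    return SubstitutionModel(
        family=fam,
        freqs=np.asarray(freqs, dtype=float),
        exchangeabilities=s,
        alpha=alpha,
        ncat=ncat,
    )


def discrete_gamma_category_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equiprobable discrete-gamma categories.

    The gamma has shape ``alpha`` and mean 1; category means are computed
    from the incomplete-gamma identity and renormalized to average
    exactly 1.
    """
    if alpha <= 0:
        raise InvalidModelError("alpha must be > 0")
    if ncat < 1:
        raise InvalidModelError("ncat must be >= 1")
    if ncat == 1:
        return np.ones(1)
    edges = sps.gamma.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1.0 / alpha)
    # E[X; X in (l,u)] for Gamma(a, theta) is a*theta*[F_{a+1}(u)-F_{a+1}(l)]
    upper_cdf = sps.gamma.cdf(edges, a=alpha + 1, scale=1.0 / alpha)
    means = ncat * np.diff(upper_cdf)
    means = np.clip(means, 0.0, None)
    return means / means.mean()


def draw_site_rates(
    alpha: float | None, ncat: int, length: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-site rate multipliers under the discrete-gamma model."""
    if length < 1:
        raise InvalidParameterError("length must be >= 1")
    if alpha is None:
        return np.ones(length)
    cats = discrete_gamma_category_rates(alpha, ncat)
    return cats[rng.integers(0, ncat, size=length)]


@dataclass(frozen=True)
class Alignment:
    """A rectangular nucleotide alignment.

    ``data`` holds base codes (A=0, C=1, G=2, T=3) as an
    ``(n_sequences, length)`` uint8 matrix.
    """

    data: np.ndarray
    labels: tuple[str, ...]
    partition: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise InvalidParameterError("alignment matrix must be 2-D")
        if len(self.labels) != self.data.shape[0]:
            raise InvalidParameterError("one label per sequence required")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError("duplicate sequence labels")

    @property
    def n_sequences(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, i: int) -> str:
        return "".join(BASES[c] for c in self.data[i])

    @classmethod
    def from_strings(
        cls, labels: list[str], seqs: list[str], partition: str = ""
    ) -> "Alignment":
        if not seqs:
            raise InvalidParameterError("empty alignment")
        lens = {len(s) for s in seqs}
        if len(lens) != 1:
            ragged = [l for l, s in zip(labels, seqs)
                      if len(s) != len(seqs[0])][0]
            raise InvalidParameterError(
                f"ragged alignment: sequence {ragged!r} has a different length"
            )
        n, L = len(seqs), len(seqs[0])
        data = np.empty((n, L), dtype=np.uint8)
        for i, s in enumerate(seqs):
            s = s.upper().replace("U", "T")
            for j, ch in enumerate(s):
                code = _BASE_TO_CODE.get(ch)
                if code is None:
                    code = 255  # ambiguity/gap marker
                data[i, j] = code
        return cls(data=data, labels=tuple(labels), partition=partition)


def evolve_alignment(
    g: Genealogy,
    model: SubstitutionModel,
    length: int,
    mu: float,
    rng: np.random.Generator,
    partition: str = "",
) -> Alignment:
    """Evolve sequences down a genealogy; returns leaf sequences only.

    ``mu`` is the mutation rate per site per generation at rate-1 sites;
    branch lengths are taken from the genealogy's node times.
    """
    if length <= 0:
        raise InvalidParameterError("length must be > 0")
    if mu < 0:
        raise InvalidParameterError("mu must be >= 0")

    n = g.n_leaves
    root_seq = rng.choice(4, size=length, p=model.freqs).astype(np.uint8)
    if mu == 0 or n == 0:
        data = np.tile(root_seq, (n, 1))
        return Alignment(data=data, labels=tuple(g.leaf_labels()),
                         partition=partition)

    site_rates = draw_site_rates(model.alpha, model.ncat, length, rng)
    Q = model.rate_matrix
    qmax = float(np.max(-np.diag(Q)))
    jump = np.eye(4) + Q / qmax
    jump_cum = np.cumsum(jump, axis=1)

    # sample virtual events jointly over branches and sites
    parent = g.parent
    branch_nodes = np.flatnonzero(parent >= 0)
    blen = g.time[parent[branch_nodes]] - g.time[branch_nodes]
    total_len = float(blen.sum())
    R = float(site_rates.sum())
    n_events = rng.poisson(mu * qmax * R * total_len)

    events_by_node: dict[int, list[int]] = {}
    if n_events > 0 and total_len > 0:
        ev_branch = rng.choice(len(branch_nodes), size=n_events,
                               p=blen / total_len)
        ev_site = rng.choice(length, size=n_events, p=site_rates / R)
        for b, s in zip(ev_branch, ev_site):
            events_by_node.setdefault(int(branch_nodes[b]), []).append(int(s))

    children: dict[int, list[int]] = {}
    root = -1
    for i in range(g.n_nodes):
        p = int(parent[i])
        if p == -1:
            root = i
        else:
            children.setdefault(p, []).append(i)

    data = np.empty((n, length), dtype=np.uint8)
    seq = root_seq.copy()
    # iterative DFS with an undo stack so the working sequence is shared
    stack: list[tuple[int, list[tuple[int, int]]]] = [(root, [])]
    while stack:
        node, undo = stack.pop()
        if node < 0:  # sentinel: revert this subtree's edits
            for s, old in reversed(undo):
                seq[s] = old
            continue
        for s in events_by_node.get(node, ()):
            old = int(seq[s])
            u = rng.random()
            new = int(np.searchsorted(jump_cum[old], u, side="right"))
            if new > 3:
                new = 3
            undo.append((s, old))
            seq[s] = new
        if node < n:
            data[node] = seq
        stack.append((-1, undo))
        for c in children.get(node, ()):
            stack.append((c, []))
    return Alignment(data=data, labels=tuple(g.leaf_labels()),
                     partition=partition)
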