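"""Synthetic training data: random trees, substitution models, and MSAs.

The generator emulates the kind of heterogeneous, empirically derived data
used to train branch-support classifiers: tree shapes from a Yule (pure
birth) process whose branch lengths are jittered by lognormal rate noise
and rescaled so that total tree divergence spans roughly [0.5, 20]
substitutions/site, and GTR+Gamma models with Dirichlet base frequencies
and log-uniform exchangeabilities.  Everything is driven by explicit seeds
and is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import gamma as gamma_dist

from .phylo import Tree

NUC = "ACGT"
NUC_TO_CODE = {c: i for i, c in enumerate(NUC)}
GAP_CODE = 4

# exchangeability order: AC, AG, AT, CG, CT, GT
_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionModel:
    """GTR exchangeabilities + base frequencies + Gamma shape + p-inv.

    ``rates`` follow the conventional AC, AG, AT, CG, CT, GT order and are
    normalized to unit mean; the rate matrix is scaled so one unit of
    branch length equals one expected substitution per site.
    """

    rates: np.ndarray
    freqs: np.ndarray
    alpha: Optional[float] = None
    pinv: float = 0.0
    ncat: int = 4

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise SimulationError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise SimulationError("need 4 positive base frequencies")
        self.rates = self.rates / self.rates.mean()
        self.freqs = self.freqs / self.freqs.sum()
        if not (0.0 <= self.pinv < 1.0):
            raise SimulationError("pinv must be in [0, 1)")
        if self.alpha is not None and not (self.alpha > 0):
            raise SimulationError("alpha must be positive")

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        return cls(rates=np.ones(6), freqs=np.full(4, 0.25))

    def q_matrix(self) -> np.ndarray:
        """Scaled GTR rate matrix: zero row sums, mean rate 1."""
        Q = np.zeros((4, 4))
        for r, (i, j) in zip(self.rates, _PAIRS):
            Q[i, j] = r * self.freqs[j]
            Q[j, i] = r * self.freqs[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(self.freqs, np.diag(Q)))
        return Q / mu

    def eigensystem(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(V, Vinv, lam) with Q = V diag(lam) Vinv, via the
        frequency-symmetrized basis (numerically stable for any GTR)."""
        Q = self.q_matrix()
        sq = np.sqrt(self.freqs)
        B = Q * (sq[:, None] / sq[None, :])
        B = 0.5 * (B + B.T)
        lam, U = np.linalg.eigh(B)
        V = U / sq[:, None]
        Vinv = U.T * sq[None, :]
        return V, Vinv, lam

    def category_rates(self) -> np.ndarray:
        """Mean-one discrete-Gamma category rates, inflated by 1/(1-pinv)
        so that the full mixture (invariant class included) has mean 1."""
        if self.alpha is None or np.isinf(self.alpha):
            r = np.ones(1)
        else:
            a = self.alpha
            edges = gamma_dist.ppf(
                np.linspace(0, 1, self.ncat + 1), a, scale=1.0 / a
            )
            upper = gamma_dist.cdf(edges[1:], a + 1, scale=1.0 / a)
            lower = gamma_dist.cdf(edges[:-1], a + 1, scale=1.0 / a)
            r = (upper - lower) * self.ncat
            r = np.clip(r, 1e-8, None)
            r = r / r.mean()
        return r / (1.0 - self.pinv)

    def to_dict(self) -> dict:
        return {
            "rates": self.rates.tolist(),
            "freqs": self.freqs.tolist(),
            "alpha": self.alpha,
            "pinv": self.pinv,
            "ncat": self.ncat,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SubstitutionModel":
        return cls(
            rates=np.asarray(d["rates"]),
            freqs=np.asarray(d["freqs"]),
            alpha=d.get("alpha"),
            pinv=d.get("pinv", 0.0),
            ncat=d.get("ncat", 4),
        )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data.

    Defaults are the desk-scale reduction of the full design: 8-64 taxa and
    100-2000 sites per MSA (the full design used 30-1000 taxa and up to
    10000 sites), GTR+Gamma models with realistic parameter spreads, and
    Yule tree shapes rescaled to total divergences log-uniform in
    [0.5, 20].
    """

    ntaxa_range: Tuple[int, int] = (8, 64)
    nsites_range: Tuple[int, int] = (100, 2000)
    freq_concentration: float = 20.0
    exch_log_range: Tuple[float, float] = (0.25, 4.0)
    alpha_range: Tuple[float, float] = (0.25, 4.0)
    pinv_range: Tuple[float, float] = (0.0, 0.0)
    ncat: int = 4
    birth_rate: float = 1.0
    death_rate: float = 0.0
    divergence_range: Tuple[float, float] = (0.5, 20.0)
    rate_noise_sigma: float = 0.4
    msas_per_tree: int = 1
    model_override: Optional[str] = None  # None | "jc"

    def validate(self) -> None:
        for lo, hi in (
            self.ntaxa_range,
            self.nsites_range,
            self.divergence_range,
        ):
            if not (0 < lo <= hi):
                raise SimulationError("empty or invalid range")
        if self.ntaxa_range[0] < 4:
            raise SimulationError("need at least 4 taxa")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Tree sampling
# ---------------------------------------------------------------------------


def _taxon_labels(ntaxa: int) -> List[str]:
    width = len(str(ntaxa))
    return ["t%0*d" % (width, i + 1) for i in range(ntaxa)]


def sample_tree(ntaxa: int, config: SimulationConfig, seed: int) -> Tree:
    """Random unrooted binary tree with realistic branch lengths.

    Topology and node times follow a Yule process (uniform random joins
    with exponential epoch durations); per-branch lognormal rate noise
    breaks the clock, and all lengths are rescaled so total divergence hits
    a target drawn log-uniformly from ``config.divergence_range``.
    """
    if ntaxa < 4:
        raise SimulationError("ntaxa must be >= 4")
    rng = np.random.default_rng(seed)
    labels = _taxon_labels(ntaxa)

    # backward construction: tips at time 0, merge uniform pairs
    n = ntaxa
    next_id = n
    times = {i: 0.0 for i in range(n)}
    active = list(range(n))
    adj = {i: [] for i in range(n)}
    t = 0.0
    lam = config.birth_rate
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / (lam * k))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        node = next_id
        next_id += 1
        adj[node] = []
        for child in (a, b):
            ln = t - times[child]
            adj[node].append((child, ln))
            adj[child].append((node, ln))
        times[node] = t
        active = [x for x in active if x not in (a, b)] + [node]

    # the root of the backward construction has degree 2: suppress it
    root = active[0]
    (a, la), (b, lb) = adj[root]
    adj[a] = [(w, l) for (w, l) in adj[a] if w != root]
    adj[b] = [(w, l) for (w, l) in adj[b] if w != root]
    adj[a].append((b, la + lb))
    adj[b].append((a, la + lb))
    del adj[root]

    tree = Tree.from_adjacency(labels, adj)

    # rate noise, then rescale to the drawn total divergence
    sigma = config.rate_noise_sigma
    if sigma > 0:
        noise = rng.lognormal(0.0, sigma, size=tree.n_nodes)
        tree.blen = tree.blen * noise
        tree.blen[tree.root] = 0.0
        if tree.n_leaves > 2:
            tree.blen[0] = 0.0
    lo, hi = config.divergence_range
    target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    total = tree.total_divergence()
    if total > 0:
        tree.blen = tree.blen * (target / total)
    return tree


# ---------------------------------------------------------------------------
# Model sampling
# ---------------------------------------------------------------------------


def sample_model(config: SimulationConfig, seed: int) -> SubstitutionModel:
    rng = np.random.default_rng(seed)
    if config.model_override == "jc":
        return SubstitutionModel.jc()
    lo, hi = config.exch_log_range
    rates = np.exp(rng.uniform(np.log(lo), np.log(hi), size=6))
    freqs = rng.dirichlet(np.full(4, config.freq_concentration))
    freqs = np.clip(freqs, 1e-4, None)
    alo, ahi = config.alpha_range
    alpha = float(np.exp(rng.uniform(np.log(alo), np.log(ahi))))
    plo, phi = config.pinv_range
    pinv = float(rng.uniform(plo, phi))
    return SubstitutionModel(
        rates=rates, freqs=freqs, alpha=alpha, pinv=pinv, ncat=config.ncat
    )


# ---------------------------------------------------------------------------
# MSA
# ---------------------------------------------------------------------------


@dataclass
class MSA:
    labels: List[str]
    codes: np.ndarray  # uint8 [n_seqs, n_sites], 0..3 = ACGT, 4 = gap/other

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.labels):
            raise SimulationError("codes shape does not match labels")

    @property
    def n_seqs(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def sequence(self, i: int) -> str:
        alphabet = np.array(list(NUC + "-"))
        return "".join(alphabet[self.codes[i]])

    def to_fasta(self) -> str:
        out = []
        for i, lb in enumerate(self.labels):
            out.append(">" + lb)
            out.append(self.sequence(i))
        return "\n".join(out) + "\n"

    @classmethod
    def from_fasta(cls, text: str) -> "MSA":
        from Bio import SeqIO
        import io as _io

        labels, rows = [], []
        for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
            labels.append(rec.id)
            seq = str(rec.seq).upper()
            row = np.full(len(seq), GAP_CODE, dtype=np.uint8)
            for ch, code in NUC_TO_CODE.items():
                row[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(ch)] = code
            row[np.frombuffer(seq.encode(), dtype=np.uint8) == ord("U")] = 3
            rows.append(row)
        if not rows:
            raise SimulationError("no sequences in FASTA")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise SimulationError("sequences have unequal lengths")
        return cls(labels=labels, codes=np.vstack(rows))


def simulate_msa(
    tree: Tree, model: SubstitutionModel, nsites: int, seed: int
) -> MSA:
    """Evolve ``nsites`` DNA characters along ``tree`` under ``model``.

    Root states are drawn from the stationary frequencies; each site gets a
    rate from the discrete-Gamma / invariant mixture; characters transition
    along each branch with matrix-exponential probabilities.
    """
    if nsites < 1:
        raise SimulationError("nsites must be >= 1")
    rng = np.random.default_rng(seed)
    V, Vinv, lam = model.eigensystem()
    crates = model.category_rates()
    ncat = crates.size

    # per-site rates (invariant class has rate 0)
    if model.pinv > 0:
        probs = np.concatenate(
            [[model.pinv], np.full(ncat, (1 - model.pinv) / ncat)]
        )
        site_rates_pool = np.concatenate([[0.0], crates])
    else:
        probs = np.full(ncat, 1.0 / ncat)
        site_rates_pool = crates
    cat_idx = rng.choice(site_rates_pool.size, size=nsites, p=probs)

    n = tree.n_leaves
    states = np.empty((tree.n_nodes, nsites), dtype=np.uint8)
    root_states = rng.choice(4, size=nsites, p=model.freqs)
    states[tree.root] = root_states

    order = [u for u in reversed(tree.postorder()) if u != tree.root]
    unique_cats = np.arange(site_rates_pool.size)
    for u in order:
        t = float(tree.blen[u])
        parent_states = states[tree.parent[u]]
        child = np.empty(nsites, dtype=np.uint8)
        for c in unique_cats:
            m = cat_idx == c
            if not m.any():
                continue
            r = site_rates_pool[c]
            if t * r <= 0:
                child[m] = parent_states[m]
                continue
            P = (V * np.exp(lam * t * r)[None, :]) @ Vinv
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            cum = np.cumsum(P, axis=1)
            u01 = rng.random(int(m.sum()))
            child[m] = (cum[parent_states[m]] < u01[:, None]).sum(axis=1)
        states[u] = child

    return MSA(labels=list(tree.labels), codes=states[:n])


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedReplicate:
    rep_id: str
    tree: Tree
    model: SubstitutionModel
    msa: MSA
    seed: int

    def __iter__(self):
        return iter((self.tree, self.model, self.msa))


def generate_dataset(
    n_msas: int, config: SimulationConfig, seed: int
) -> List[SimulatedReplicate]:
    """Independent (true tree, model, MSA) triples.

    ``config.msas_per_tree`` > 1 reuses each tree/model for several MSAs;
    ``config.model_override`` forces the simulation model (e.g. "jc") to
    build misspecification scenarios.
    """
    if n_msas < 1:
        raise SimulationError("n_msas must be >= 1")
    config.validate()
    root_ss = np.random.SeedSequence(seed)
    out: List[SimulatedReplicate] = []
    n_trees = (n_msas + config.msas_per_tree - 1) // config.msas_per_tree
    tree_seqs = root_ss.spawn(n_trees)
    for ti in range(n_trees):
        s_tree, s_model, s_size, *s_msas = tree_seqs[ti].spawn(
            3 + config.msas_per_tree
        )
        rng = np.random.default_rng(s_size)
        ntaxa = int(rng.integers(config.ntaxa_range[0], config.ntaxa_range[1] + 1))
        tree = sample_tree(ntaxa, config, _small_seed(s_tree))
        model = sample_model(config, _small_seed(s_model))
        for mi in range(config.msas_per_tree):
            if len(out) >= n_msas:
                break
            nsites = int(
                np.random.default_rng(s_msas[mi]).integers(
                    config.nsites_range[0], config.nsites_range[1] + 1
                )
            )
            mseed = _small_seed(s_msas[mi])
            msa = simulate_msa(tree, model, nsites, mseed)
            out.append(
                SimulatedReplicate(
                    rep_id=f"rep{len(out):05d}",
                    tree=tree,
                    model=model,
                    msa=msa,
                    seed=mseed,
                )
            )
    return out


def _small_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def write_replicate(directory, rep: SimulatedReplicate) -> None:
    """FASTA + Newick + JSON sidecar for one replicate."""
    import os

    os.makedirs(directory, exist_ok=True)
    base = os.path.join(directory, rep.rep_id)
    with open(base + ".fasta", "w") as fh:
        fh.write(rep.msa.to_fasta())
    with open(base + ".nwk", "w") as fh:
        fh.write(rep.tree.to_newick() + "\n")
    with open(base + ".json", "w") as fh:
        json.dump({"model": rep.model.to_dict(), "seed": rep.seed}, fh, indent=1)
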