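"""Synthetic data generators for validating every analysis stage.

Three stochastic generators and one deterministic fixture bundle:

* :func:`simulate_neutral_sample` — a sample from the standard neutral
  coalescent (Hudson construction: exponential coalescence times at rate
  k(k−1)/2 in units of 2N generations) with Poisson(θ·branch/2) mutations
  under the infinite-sites model, mapped onto a random monomorphic
  nucleotide background.  Validates Tajima/Fu–Li null behaviour
  (E[S] = θ·a1, E[π] = θ).
* :func:`simulate_codon_sample` — the same genealogy over a codon
  alignment: single-nucleotide changes are proposed uniformly along
  branches; synonymous proposals are always accepted, non-synonymous ones
  with probability min(1, ω), stops always rejected.  Realised dN/dS is
  therefore ≈ ω by construction (an acceptance filter, not a full codon
  model).  An outgroup sequence diverges from the root along a branch
  with ``t_div`` expected proposals per site, providing fixed differences
  for divergence and MK validation.
* :func:`simulate_ssr_genotypes` — multiallelic diploid genotypes under
  Hardy–Weinberg sampling; designated locus pairs can be made biallelic
  with a prescribed normalised association D′ between them.
* :func:`fixture_worked_examples` — tiny hand-countable datasets with
  expected-output manifests.

Every stochastic call derives its generator from ``cfg.seed`` alone, so
results are bit-reproducible and order-independent across operations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .alignment import Alignment, CodonAlignment, SequenceRecord, STOP_CODONS
from .ssr import GenotypeTable

__all__ = [
    "SimConfig",
    "simulate_neutral_sample",
    "simulate_codon_sample",
    "simulate_ssr_genotypes",
    "fixture_worked_examples",
]

_NUCS = "ACGT"

#: Default per-locus allele counts for the SSR generator: ten loci around
#: a self-incompatibility locus, with the observed allele richness of a
#: small (n=24) germplasm panel.
DEFAULT_SSR_ALLELE_COUNTS = (6, 3, 5, 4, 3, 5, 4, 2, 4, 3)


def _geometric_freqs(k: int, ratio: float = 0.3) -> tuple[float, ...]:
    w = np.array([ratio**i for i in range(k)])
    return tuple(w / w.sum())


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic-data generators.

    Defaults emulate the study conditions the package is tested under:
    n = 13 sequences per allele class, θ large enough to give a few
    hundred variable sites on a ~1 kb coding region, 24 diploid
    individuals at 10 SSR loci.
    """

    seed: int
    n: int = 13                      # sample size (sequences or individuals)
    theta: float = 5.0               # population mutation parameter per locus
    L: int = 1000                    # sequence length (nt, or codons for codon mode)
    omega: float = 1.0               # nonsyn/syn acceptance ratio
    t_div: float = 0.05              # outgroup divergence, expected proposals/site
    ssr_freqs: tuple[tuple[float, ...], ...] | None = None
    d_prime: float = 0.0             # association for the first SSR locus pair
    n_individuals: int = 24
    max_retries: int = 10

    def __post_init__(self) -> None:
        if self.theta < 0 or self.omega < 0 or self.t_div < 0:
            raise ValueError("rates must be non-negative")
        if self.ssr_freqs is not None:
            for f in self.ssr_freqs:
                if abs(sum(f) - 1.0) > 1e-9:
                    raise ValueError("allele frequencies must sum to 1 per locus")

    def locus_freqs(self) -> tuple[tuple[float, ...], ...]:
        if self.ssr_freqs is not None:
            return self.ssr_freqs
        return tuple(_geometric_freqs(k) for k in DEFAULT_SSR_ALLELE_COUNTS)


# ---------------------------------------------------------------------------
# Coalescent machinery
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Genealogy:
    """A coalescent tree over 2n−1 nodes (leaves 0..n−1, root last)."""

    n: int
    children: list[tuple[int, int] | None]  # per node; None for leaves
    times: list[float]
    parent: list[int | None]

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return 0.0 if p is None else self.times[p] - self.times[node]

    def leaves_below(self, node: int) -> list[int]:
        ch = self.children[node]
        if ch is None:
            return [node]
        return self.leaves_below(ch[0]) + self.leaves_below(ch[1])

    def total_length(self) -> float:
        return sum(self.branch_length(v) for v in range(2 * self.n - 2))


def _coalescent(n: int, rng: np.random.Generator) -> _Genealogy:
    """Hudson construction of a standard neutral coalescent genealogy."""
    n_nodes = 2 * n - 1
    children: list[tuple[int, int] | None] = [None] * n_nodes
    times = [0.0] * n_nodes
    parent: list[int | None] = [None] * n_nodes
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        children[nxt] = (a, b)
        times[nxt] = t
        parent[a] = parent[b] = nxt
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
        k -= 1
    return _Genealogy(n=n, children=children, times=times, parent=parent)


def simulate_neutral_sample(cfg: SimConfig) -> Alignment:
    """Neutral coalescent sample under the infinite-sites model.

    Each mutation is assigned a distinct alignment position (sampled
    without replacement) and a single derived state; the mutation count
    is redrawn up to ``cfg.max_retries`` times if it exceeds the sequence
    length, and an error raised afterwards.
    """
    if cfg.n < 2:
        raise ValueError("n >= 2 required")
    rng = np.random.default_rng(cfg.seed)
    tree = _coalescent(cfg.n, rng)
    background = rng.choice(list(_NUCS), size=cfg.L)
    branch_nodes = [v for v in range(2 * cfg.n - 2)]
    lengths = np.array([tree.branch_length(v) for v in branch_nodes])
    total = lengths.sum()
    for _ in range(cfg.max_retries):
        n_mut = rng.poisson(cfg.theta * total / 2.0) if cfg.theta > 0 else 0
        if n_mut <= cfg.L:
            break
    else:
        raise ValueError(
            f"could not place {n_mut} infinite-site mutations on L={cfg.L}; "
            "increase L or lower theta"
        )
    seqs = np.tile(background, (cfg.n, 1))
    if n_mut > 0:
        sites = rng.choice(cfg.L, size=n_mut, replace=False)
        probs = lengths / total
        carriers = rng.choice(len(branch_nodes), size=n_mut, p=probs)
        for site, bi in zip(sites, carriers):
            anc = background[site]
            derived = rng.choice([c for c in _NUCS if c != anc])
            for leaf in tree.leaves_below(branch_nodes[bi]):
                seqs[leaf, site] = derived
    records = tuple(
        SequenceRecord(f"seq{i + 1}", "".join(seqs[i])) for i in range(cfg.n)
    )
    return Alignment(records, kind="nucleotide")


# ---------------------------------------------------------------------------
# Codon model with acceptance-filtered omega
# ---------------------------------------------------------------------------

from .alignment import _STANDARD_TABLE  # noqa: E402

_AA = dict(_STANDARD_TABLE.forward_table)


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> list[str]:
    sense = sorted(_AA)
    idx = rng.integers(0, len(sense), size=n_codons)
    return [sense[i] for i in idx]


def _evolve(seq: list[str], n_prop: int, omega: float,
            rng: np.random.Generator) -> list[str]:
    """Apply ``n_prop`` proposed single-nt changes with the ω filter."""
    seq = list(seq)
    L3 = 3 * len(seq)
    for _ in range(n_prop):
        pos = int(rng.integers(0, L3))
        ci, off = divmod(pos, 3)
        codon = seq[ci]
        alt = _NUCS[int(rng.integers(0, 4))]
        if alt == codon[off]:
            continue
        mut = codon[:off] + alt + codon[off + 1 :]
        if mut in STOP_CODONS:
            continue
        if _AA[mut] != _AA[codon] and omega < 1.0 and rng.random() >= omega:
            continue
        seq[ci] = mut
    return seq


def simulate_codon_sample(cfg: SimConfig) -> tuple[CodonAlignment, Alignment]:
    """Codon alignment with acceptance-controlled ω plus a diverged outgroup.

    ``cfg.L`` is in codons; ``cfg.theta`` scales the proposal intensity
    on the sample genealogy (Poisson(θ·branch/2) proposals per branch);
    the outgroup receives Poisson(t_div · 3L) proposals on its own branch
    from the root.  Stop codons never occur in the output.
    """
    if cfg.n < 2:
        raise ValueError("n >= 2 required")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    tree = _coalescent(cfg.n, rng)
    root_seq = _random_coding_sequence(cfg.L, rng)
    seqs: dict[int, list[str]] = {tree.root: root_seq}
    # pre-order walk applying mutations along each branch
    stack = [tree.root]
    while stack:
        node = stack.pop()
        ch = tree.children[node]
        if ch is None:
            continue
        for child in ch:
            n_prop = rng.poisson(cfg.theta * tree.branch_length(child) / 2.0)
            seqs[child] = _evolve(seqs[node], n_prop, cfg.omega, rng)
            stack.append(child)
    n_out = rng.poisson(cfg.t_div * 3 * cfg.L)
    out_seq = _evolve(root_seq, n_out, cfg.omega, rng)
    records = tuple(
        SequenceRecord(f"seq{i + 1}", "".join(seqs[i])) for i in range(cfg.n)
    )
    focal = CodonAlignment(Alignment(records, kind="nucleotide"))
    outgroup = Alignment(
        (SequenceRecord("outgroup", "".join(out_seq)),), kind="nucleotide"
    )
    return focal, outgroup


# ---------------------------------------------------------------------------
# SSR genotypes
# ---------------------------------------------------------------------------

def simulate_ssr_genotypes(cfg: SimConfig) -> GenotypeTable:
    """HWE diploid genotypes at multiallelic loci, optional two-locus LD.

    With ``cfg.d_prime != 0`` the first two loci are made biallelic (their
    first two renormalised frequencies) and two-locus haplotypes drawn
    with gametic disequilibrium ``D = d_prime · D_max``; an infeasible
    D′ raises with the feasible bound.  All other loci are independent.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    freqs = cfg.locus_freqs()
    n_ind = cfg.n_individuals
    loci = tuple(f"locus{i + 1}" for i in range(len(freqs)))
    individuals = tuple(f"ind{i + 1}" for i in range(n_ind))
    calls: dict[tuple[str, str], tuple[str, str] | None] = {}

    linked = cfg.d_prime != 0.0 and len(freqs) >= 2
    hap_pool: np.ndarray | None = None
    if linked:
        pa = freqs[0][0] / (freqs[0][0] + freqs[0][1])
        pb = freqs[1][0] / (freqs[1][0] + freqs[1][1])
        if cfg.d_prime > 0:
            d_max = min(pa * (1 - pb), (1 - pa) * pb)
        else:
            d_max = min(pa * pb, (1 - pa) * (1 - pb))
        D = cfg.d_prime * d_max
        probs = np.array([
            pa * pb + D,            # A1 B1
            pa * (1 - pb) - D,      # A1 B2
            (1 - pa) * pb - D,      # A2 B1
            (1 - pa) * (1 - pb) + D,
        ])
        if (probs < -1e-12).any():
            raise ValueError(
                f"d_prime={cfg.d_prime} infeasible for freqs ({pa:.3f}, {pb:.3f}); "
                f"|D| must be <= {d_max:.4f}"
            )
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        hap_pool = rng.choice(4, size=(n_ind, 2), p=probs)

    for li, locus in enumerate(loci):
        p = np.array(freqs[li])
        labels = [str(101 + 2 * a) for a in range(len(p))]  # SSR-style allele sizes
        if linked and li < 2:
            # haplotype codes 0..3: bit for locus 0 is code//2, locus 1 is code%2
            for ind_i, ind in enumerate(individuals):
                h1, h2 = hap_pool[ind_i]
                bit1 = h1 // 2 if li == 0 else h1 % 2
                bit2 = h2 // 2 if li == 0 else h2 % 2
                calls[(ind, locus)] = tuple(sorted((labels[bit1], labels[bit2])))
        else:
            draws = rng.choice(len(p), size=(n_ind, 2), p=p / p.sum())
            for ind_i, ind in enumerate(individuals):
                a, b = draws[ind_i]
                calls[(ind, locus)] = tuple(sorted((labels[a], labels[b])))
    return GenotypeTable(individuals=individuals, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures
# ---------------------------------------------------------------------------

def fixture_worked_examples() -> dict[str, dict]:
    """Tiny hand-countable datasets, each with an expected-output manifest.

    Deterministic by construction (no RNG), so regeneration is always
    byte-identical.
    """
    spectrum = Alignment(
        (
            SequenceRecord("s1", "AAAA"),
            SequenceRecord("s2", "AAAA"),
            SequenceRecord("s3", "AGAA"),
            SequenceRecord("s4", "AGAT"),
        ),
        kind="nucleotide",
    )
    codon_pair = ("TTT", "GTA")
    upgma_labels = ("A", "B", "C")
    upgma_matrix = np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 4.0], [4.0, 4.0, 0.0]])
    haplotypes = Alignment(
        (
            SequenceRecord("h1", "AAA"),
            SequenceRecord("h2", "ATA"),
            SequenceRecord("h3", "AAT"),
            SequenceRecord("h4", "ATT"),
        ),
        kind="nucleotide",
    )
    genotypes = GenotypeTable(
        individuals=("i1", "i2", "i3", "i4"),
        loci=("L1",),
        calls={
            ("i1", "L1"): ("A", "B"),
            ("i2", "L1"): ("A", "B"),
            ("i3", "L1"): ("A", "A"),
            ("i4", "L1"): ("B", "B"),
        },
    )
    return {
        "site_spectrum_4seq": {
            "data": spectrum,
            "manifest": {"S": 2, "eta": 2, "singletons": 1,
                         "parsimony_informative": 1},
        },
        "codon_pathway_pair": {
            "data": codon_pair,
            "manifest": {"Nd": 1.5, "Ns": 0.5},
        },
        "upgma_3taxa": {
            "data": (upgma_labels, upgma_matrix),
            "manifest": {"newick": "((A:1.000000,B:1.000000):1.000000,C:2.000000);",
                         "heights": {"AB": 1.0, "ABC": 2.0}},
        },
        "haplotype_cycle_4": {
            "data": haplotypes,
            "manifest": {"n_nodes": 4, "n_edges": 4, "all_weights_one": True,
                         "mst_length": 3},
        },
        "genotype_2allele_4ind": {
            "data": genotypes,
            "manifest": {"Ao": 2, "Ho": 0.5, "He_plain": 0.5, "PD": 0.625},
        },
    }
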