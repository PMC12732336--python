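"""Synthetic organism-like CDS generation.

Genes are sampled from a first-order codon Markov chain over the 61 sense
codons: an organism is characterized by its codon marginal frequencies
(species-specific codon usage bias), a codon-to-codon transition matrix
(adjacent-codon correlations), and a gene-length law.  Stop codons never
appear in the gene body by construction; an optional terminal stop can be
appended.  Divergence between organisms is controlled by perturbing the
codon marginals in log space, which lets the rest of the pipeline be
exercised at any chosen effect size without genome downloads.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .core import SENSE_CODONS
from .seqio import CdsRecord

#: Concentration of the Dirichlet used for transition-row perturbations.
#: Rows are drawn around the codon marginals so the chain's stationary law
#: stays close to them even with strong adjacent-codon correlation.
ROW_CONCENTRATION = 50.0


@dataclass(frozen=True)
class LengthLaw:
    """Gene length distribution, in codons.

    Log-normal with the given median and log-scale sigma, truncated to
    [min_codons, max_codons] by resampling.
    """

    family: str = "lognormal"
    median: float = 300.0
    sigma: float = 0.5
    min_codons: int = 30
    max_codons: int = 3000

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family != "lognormal":
            raise ValueError(f"unknown length law: {self.family!r}")
        out = np.empty(n, dtype=int)
        remaining = np.arange(n)
        while remaining.size:
            draw = rng.lognormal(np.log(self.median), self.sigma,
                                 size=remaining.size)
            lengths = np.round(draw).astype(int)
            ok = (lengths >= self.min_codons) & (lengths <= self.max_codons)
            out[remaining[ok]] = lengths[ok]
            remaining = remaining[~ok]
        return out


@dataclass(frozen=True)
class OrganismProfile:
    """Generative model of one synthetic organism's coding sequences."""

    label: str
    codon_probs: np.ndarray          # length-61, sums to 1
    transition: np.ndarray           # 61 x 61 row-stochastic
    length_law: LengthLaw
    seed: int
    skew: Optional[float] = None
    correlation: Optional[float] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.codon_probs, dtype=float)
        T = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "codon_probs", p)
        object.__setattr__(self, "transition", T)
        if p.shape != (61,):
            raise ValueError("codon_probs must have length 61")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("codon_probs must be a probability vector")
        if T.shape != (61, 61):
            raise ValueError("transition must be 61 x 61")
        if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition rows must each sum to 1")

    def to_json(self) -> str:
        return json.dumps({
            "label": self.label,
            "codon_probs": self.codon_probs.tolist(),
            "transition": self.transition.tolist(),
            "length_law": asdict(self.length_law),
            "seed": self.seed,
            "skew": self.skew,
            "correlation": self.correlation,
        })

    @classmethod
    def from_json(cls, text: str) -> "OrganismProfile":
        d = json.loads(text)
        return cls(label=d["label"],
                   codon_probs=np.asarray(d["codon_probs"]),
                   transition=np.asarray(d["transition"]),
                   length_law=LengthLaw(**d["length_law"]),
                   seed=int(d["seed"]),
                   skew=d.get("skew"),
                   correlation=d.get("correlation"))


def _random_row_stochastic(marginals: np.ndarray,
                           rng: np.random.Generator) -> np.ndarray:
    """61 independent rows drawn around the marginals.

    Each row ~ Dirichlet(marginals * ROW_CONCENTRATION), so E[row] equals
    the marginals and the induced chain stays near-stationary at them.
    """
    alpha = marginals * ROW_CONCENTRATION + 1e-6
    return rng.dirichlet(alpha, size=61)


def _build_transition(codon_probs: np.ndarray, correlation: float,
                      rng: np.random.Generator) -> np.ndarray:
    base = np.tile(codon_probs, (61, 1))
    if correlation == 0.0:
        return base
    noise = _random_row_stochastic(codon_probs, rng)
    T = (1.0 - correlation) * base + correlation * noise
    return T / T.sum(axis=1, keepdims=True)


def make_profile(seed: int, skew: float = 0.3, correlation: float = 0.3,
                 label: Optional[str] = None,
                 length_law: Optional[LengthLaw] = None) -> OrganismProfile:
    """Draw a random organism profile.

    Parameters
    ----------
    seed : int
        Drives all randomness; the same seed reproduces the profile.
    skew : float > 0
        Concentration of the symmetric Dirichlet the codon marginals are
        drawn from.  Small values give a strongly biased organism (a few
        dominant codons); large values approach uniform usage.
    correlation : float in [0, 1]
        Mixing weight of a random row-stochastic perturbation into the
        transition matrix.  0 gives independent codons (pair frequencies
        factorize); larger values give stronger adjacent-codon structure.
    """
    if skew <= 0:
        raise ValueError("skew must be > 0")
    if not (0.0 <= correlation <= 1.0):
        raise ValueError("correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codon_probs = rng.dirichlet(np.full(61, skew))
    transition = _build_transition(codon_probs, correlation, rng)
    return OrganismProfile(
        label=label or f"synthetic-{seed}",
        codon_probs=codon_probs,
        transition=transition,
        length_law=length_law or LengthLaw(),
        seed=seed,
        skew=skew,
        correlation=correlation,
    )


def perturb_profile(p: OrganismProfile, divergence: float,
                    seed: int, label: Optional[str] = None) -> OrganismProfile:
    """Derive a diverged organism from an existing profile.

    Codon marginals are multiplied by exp(divergence * N(0,1)) per codon and
    renormalized; divergence 0 returns an identical distribution, and the
    total-variation distance between old and new marginals grows
    stochastically with divergence.  The transition matrix is rebuilt around
    the new marginals with the profile's own correlation.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    rng = np.random.default_rng(seed)
    if divergence == 0.0:
        new_probs = p.codon_probs.copy()
    else:
        noise = rng.normal(0.0, 1.0, size=61)
        new_probs = p.codon_probs * np.exp(divergence * noise)
        new_probs = new_probs / new_probs.sum()
    correlation = p.correlation if p.correlation is not None else 0.0
    transition = _build_transition(new_probs, correlation, rng)
    return OrganismProfile(
        label=label or f"{p.label}+d{divergence:g}",
        codon_probs=new_probs,
        transition=transition,
        length_law=p.length_law,
        seed=seed,
        skew=p.skew,
        correlation=correlation,
    )


def sample_genome(p: OrganismProfile, n_genes: int, seed: int,
                  append_stop: bool = False) -> list[CdsRecord]:
    """Sample a synthetic genome (list of CDS records) from a profile.

    Each gene's length is drawn from the length law; the first codon comes
    from the codon marginals and each subsequent codon from the transition
    row of its predecessor.  No stop codon ever appears in the body; with
    ``append_stop`` a TAA terminal stop is added (exercising the terminal
    stop stripping of the validation policy).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = p.length_law.sample(n_genes, rng)
    max_len = int(lengths.max())

    marg_cum = np.cumsum(p.codon_probs)
    trans_cum = np.cumsum(p.transition, axis=1)

    # Vectorized chain sampling across genes: at step t only genes longer
    # than t advance; inverse-CDF lookup against the predecessor's row.
    codons = np.zeros((n_genes, max_len), dtype=np.int64)
    u0 = rng.random(n_genes)
    codons[:, 0] = np.searchsorted(marg_cum, u0, side="right").clip(max=60)
    order = np.argsort(-lengths)  # longest genes first, active prefix shrinks
    inv = np.empty_like(order)
    inv[order] = np.arange(n_genes)
    sorted_lengths = lengths[order]
    state = codons[order, 0].copy()
    samples = np.zeros((n_genes, max_len), dtype=np.int64)
    samples[:, 0] = state
    for t in range(1, max_len):
        n_active = int(np.searchsorted(-sorted_lengths, -t))
        if n_active == 0:
            break
        u = rng.random(n_active)
        rows = trans_cum[state[:n_active]]
        nxt = (rows < u[:, None]).sum(axis=1).clip(max=60)
        state[:n_active] = nxt
        samples[:n_active, t] = nxt
    codons = samples[inv]

    codon_arr = np.array(SENSE_CODONS)
    records = []
    for i in range(n_genes):
        L = int(lengths[i])
        seq = "".join(codon_arr[codons[i, :L]])
        if append_stop:
            seq += "TAA"
        records.append(CdsRecord(
            id=f"{p.label}_g{i:05d}", seq=seq, source="synthetic"))
    return records


def tv_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two codon marginal vectors."""
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())
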