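"""Forward simulation of pseudogene sequence decay.

An intact coding sequence accumulates nucleotide substitutions and small
indels at fixed per-site per-generation rates. After each mutation the
original translated protein is aligned against the evolving DNA with the
frameshift-aware translated search, and the run terminates at the first
generation where the Karlin-Altschul e-value exceeds the detection
threshold used for pseudogene mining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fishor.search.align import DEFAULT_KA, KarlinAltschulParams
from fishor.search.frameshift import encode_dna, encode_protein, frameshift_score
from fishor.search.translate import translate


def _default_indel_probs() -> np.ndarray:
    # decreasing length distribution over 1..9 bp, p(l) ~ l^-1.7
    p = np.arange(1, 10, dtype=float) ** -1.7
    return p / p.sum()


@dataclass
class DecayParams:
    mu_sub: float = 1e-8          # substitutions / site / generation
    mu_indel: float = 0.05e-8     # indels / site / generation
    ts_tv: float = 2.0            # transition:transversion count ratio
    indel_len_probs: np.ndarray = field(default_factory=_default_indel_probs)
    detect_evalue: float = 1e-20
    ka: KarlinAltschulParams = field(default_factory=lambda: DEFAULT_KA)
    max_generations: float = 1e12
    # Detection scoring. The frameshift penalty is much stricter than the
    # classification aligner's: tblastn (which the simulated detection
    # mirrors) does not bridge reading frames, so a switch is only worth
    # taking when both flanking blocks carry substantial score.
    frameshift_penalty: int = -60
    gap_penalty: int = -12

    def __post_init__(self):
        if self.mu_sub < 0 or self.mu_indel < 0:
            raise ValueError("mutation rates must be non-negative")
        probs = np.asarray(self.indel_len_probs, dtype=float)
        if probs.shape != (9,) or abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("indel_len_probs must be 9 non-negative values summing to 1")
        self.indel_len_probs = probs


@dataclass
class DecayOutcome:
    replicate: int
    generations: float
    n_substitutions: int
    n_indels: int
    final_length: int
    hit_guard: bool = False       # terminated by the max-generation guard


# transitions: A<->G (0<->2), C<->T (1<->3)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


def mutate_step(seq: np.ndarray, params: DecayParams, rng: np.random.Generator
                ) -> tuple[np.ndarray, dict]:
    """Apply exactly one mutation event to an encoded DNA sequence.

    With probability mu_sub/(mu_sub+mu_indel) a substitution is applied at
    a uniform site (transition vs transversion per ``ts_tv``); otherwise
    an indel (insertion/deletion equiprobable, length from
    ``indel_len_probs``, uniform position). Returns (new_seq, event).
    """
    if len(seq) < 1:
        raise ValueError("cannot mutate an empty sequence")
    total = params.mu_sub + params.mu_indel
    if total <= 0:
        raise ValueError("at least one mutation rate must be positive")
    if rng.random() < params.mu_sub / total:
        pos = int(rng.integers(len(seq)))
        base = seq[pos]
        if rng.random() < params.ts_tv / (params.ts_tv + 1.0):
            new = _TRANSITION[base]
            kind = "transition"
        else:
            new = _TRANSVERSIONS[base][int(rng.integers(2))]
            kind = "transversion"
        seq = seq.copy()
        seq[pos] = new
        return seq, {"type": "substitution", "kind": kind, "pos": pos}
    length = 1 + int(rng.choice(9, p=params.indel_len_probs))
    if rng.random() < 0.5 and len(seq) > 1:
        length = min(length, len(seq))
        pos = int(rng.integers(len(seq) - length + 1))
        seq = np.concatenate([seq[:pos], seq[pos + length:]])
        return seq, {"type": "deletion", "pos": pos, "length": length}
    pos = int(rng.integers(len(seq) + 1))
    ins = rng.integers(0, 4, size=length).astype(np.int8)
    seq = np.concatenate([seq[:pos], ins, seq[pos:]])
    return seq, {"type": "insertion", "pos": pos, "length": length}


def _score_threshold(params: DecayParams, m: int, n_aa: float) -> float:
    """Raw score at which the e-value equals the detection threshold."""
    return (math.log(params.ka.K * m * n_aa)
            - math.log(params.detect_evalue)) / params.ka.lam


# Upper bound on how much one mutation event can lower the best
# frameshift-aware alignment score: a <=9 nt deletion removes at most 4
# aligned codons (4 x 11) plus one frameshift penalty and boundary effects.
_MAX_SCORE_DROP_PER_EVENT = 80.0


def time_to_undetectable(cds: str, params: DecayParams | None = None,
                         seed: int | np.random.Generator = 0,
                         replicate: int = 0, check_every: int = 1) -> DecayOutcome:
    """Evolve ``cds`` until the original protein no longer detects it.

    Generations advance by exponential waiting times with total rate
    (mu_sub + mu_indel) x current length. After every mutation (or every
    ``check_every`` mutations) the translated original protein is aligned
    to the evolving DNA and the run stops once the e-value exceeds
    ``params.detect_evalue``. An exact accelerator skips alignments that
    provably cannot cross the threshold yet (each event lowers the score
    by at most a bounded amount), so results are identical to checking
    after every mutation.
    """
    params = params or DecayParams()
    if len(cds) < 300:
        raise ValueError("cds must be at least 300 nt")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    protein = translate(cds)
    if protein.endswith("*"):
        protein = protein[:-1]
    prot_codes = encode_protein(protein)
    m = len(protein)
    seq = encode_dna(cds)
    total_rate_per_site = params.mu_sub + params.mu_indel
    if total_rate_per_site <= 0:
        raise ValueError("both mutation rates are zero: the process never ends")
    generations = 0.0
    n_sub = 0
    n_indel = 0
    next_check_in = 1
    while True:
        if generations > params.max_generations:
            return DecayOutcome(replicate=replicate, generations=generations,
                                n_substitutions=n_sub, n_indels=n_indel,
                                final_length=len(seq), hit_guard=True)
        if len(seq) < 3:
            break  # nothing left to detect
        generations += rng.exponential(1.0 / (total_rate_per_site * len(seq)))
        seq, event = mutate_step(seq, params, rng)
        if event["type"] == "substitution":
            n_sub += 1
        else:
            n_indel += 1
        next_check_in -= 1
        if next_check_in > 0:
            continue
        score = frameshift_score(prot_codes, seq,
                                 frameshift_penalty=params.frameshift_penalty,
                                 gap_penalty=params.gap_penalty)
        threshold = _score_threshold(params, m, max(len(seq) / 3.0, 1.0))
        if score < threshold:
            break
        # exact skip: with the score this far above the threshold, the next
        # slack // MAX_DROP events provably cannot cross it
        slack = score - threshold
        next_check_in = max(check_every, 1 + int(slack // _MAX_SCORE_DROP_PER_EVENT))
    return DecayOutcome(replicate=replicate, generations=generations,
                        n_substitutions=n_sub, n_indels=n_indel,
                        final_length=len(seq), hit_guard=False)


@dataclass
class DecaySummary:
    n_reps: int
    median: float
    q25: float
    q75: float
    outcomes: list[DecayOutcome]

    def survival(self, generations: float) -> float:
        """Fraction of replicates still detectable at ``generations``."""
        return sum(o.generations > generations for o in self.outcomes) / self.n_reps


def decay_distribution(cds: str, params: DecayParams | None = None,
                       n_reps: int = 10_000, seed: int = 0,
                       check_every: int = 1) -> DecaySummary:
    """Replicated decay simulation with distribution summary."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    params = params or DecayParams()
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    outcomes = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        outcomes.append(time_to_undetectable(cds, params, rng, replicate=i,
                                             check_every=check_every))
    gens = np.array([o.generations for o in outcomes])
    return DecaySummary(n_reps=n_reps, median=float(np.median(gens)),
                        q25=float(np.quantile(gens, 0.25)),
                        q75=float(np.quantile(gens, 0.75)), outcomes=outcomes)
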