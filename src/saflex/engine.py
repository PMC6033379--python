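"""Exact log-space HMM inference over structural-letter sequences.

The hidden path S_1:n follows a uniform start and a homogeneous transition
matrix; each fragment emits its descriptor 4-vector from the letter's
Gaussian.  With missing descriptors the emission is the marginal (restricted)
Gaussian density on the available subset J, and a fully missing fragment
(J empty) emits density 1, leaving only the Markov context informative.
For k replicate chains sharing one hidden path (a homomer consensus), the
emission at each position is the product of the per-chain densities.

All quantities are computed in logarithmic scale with log-sum-exp, so very
low probabilities are handled exactly.  Evidence values are densities and
may exceed 1.  Outputs:

* the MAP letter sequence — jointly most probable path, via max-forward /
  max-backward recursions;
* POST — per-position marginal posterior over letters;
* ENT / NEFF — posterior entropy (nats) and its exponential, the effective
  number of acceptable letters (1 = certain, m = maximally uncertain).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .alphabet import StructuralAlphabet, StructuralLetter
from .descriptors import FragmentSeries

LOG_2PI = float(np.log(2.0 * np.pi))

EVIDENCE_CONSISTENCY_TOL = 1e-8


class EncodingFailure(RuntimeError):
    """All letters have zero likelihood at some position (evidence -inf)."""


@dataclass
class MultiChainFragmentSeries:
    """k fragment series aligned on one reference index, sharing one path.

    Position i refers to the same reference fragment in every chain; a
    reference position a chain lacks entirely simply carries J = empty for
    that chain.
    """

    per_chain: list[FragmentSeries]

    def __post_init__(self) -> None:
        if not self.per_chain:
            raise ValueError("need at least one chain")
        n = self.per_chain[0].n
        if any(s.n != n for s in self.per_chain):
            raise ValueError("all chains must have the same reference fragment count")

    @property
    def k(self) -> int:
        return len(self.per_chain)

    @property
    def n(self) -> int:
        return self.per_chain[0].n


@dataclass
class ForwardBackwardTable:
    """Log-space forward/backward and max-forward/max-backward tables."""

    log_forward: np.ndarray
    log_backward: np.ndarray
    log_max_forward: np.ndarray
    log_max_backward: np.ndarray
    log_evidence: float


@dataclass
class EncodingResult:
    """Complete encoding of one (possibly consensus) fragment series."""

    map_sequence: list[str]
    map_indices: np.ndarray
    post: np.ndarray
    ent: np.ndarray
    neff: np.ndarray
    log_evidence: float

    @property
    def n(self) -> int:
        return len(self.map_sequence)


def log_emission(letter: StructuralLetter, x, J) -> float:
    """Log density of the J-restricted Gaussian emission of one letter.

    ``x`` is a 4-vector defined (finite) on J; the value is the |J|-variate
    normal log density of x[J] under (mu[J], sigma[J, J]) including the
    -(|J|/2) log 2pi normalizing constant, which varies with |J| and must
    not be dropped.  Returns 0.0 for J = empty (density 1: the fragment is
    totally uninformative).
    """
    J = sorted(J)
    if not J:
        return 0.0
    idx = [d - 1 for d in J]
    x = np.asarray(x, dtype=float).reshape(4)[idx]
    mu = letter.mu[idx]
    sig = letter.sigma[np.ix_(idx, idx)]
    try:
        c, low = cho_factor(sig, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"letter {letter.code}: sigma[J, J] not positive definite") from exc
    diff = x - mu
    maha = float(diff @ cho_solve((c, low), diff))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return -0.5 * (len(J) * LOG_2PI + logdet + maha)


def log_emission_consensus(letter: StructuralLetter, observations) -> float:
    """Log emission for k replicate observations of one shared letter.

    ``observations`` is an iterable of (x_j, J_j); the consensus emission is
    the product of per-chain restricted Gaussian densities, so its log is
    the sum of the per-chain :func:`log_emission` terms.  Chains with
    J = empty contribute nothing.
    """
    return float(sum(log_emission(letter, x, J) for x, J in observations))


def emission_log_matrix(series: FragmentSeries | MultiChainFragmentSeries,
                        a: StructuralAlphabet) -> np.ndarray:
    """(n, m) matrix of log emissions for a series under an alphabet.

    Fragments are grouped by availability pattern so each letter's
    restricted covariance is factorized once per pattern, not per fragment.
    """
    if isinstance(series, MultiChainFragmentSeries):
        return sum(emission_log_matrix(s, a) for s in series.per_chain)
    n, m = series.n, a.m
    out = np.zeros((n, m))
    groups: dict[frozenset, list[int]] = {}
    for i, J in enumerate(series.available):
        groups.setdefault(J, []).append(i)
    for J, rows in groups.items():
        if not J:
            continue  # log e = 0 by convention
        idx = [d - 1 for d in sorted(J)]
        X = series.values[np.ix_(rows, idx)]
        for s, letter in enumerate(a.letters):
            sig = letter.sigma[np.ix_(idx, idx)]
            try:
                c, low = cho_factor(sig, lower=True)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    f"letter {letter.code}: sigma[J, J] not positive definite for J={set(J)}"
                ) from exc
            diff = X - letter.mu[idx]
            y = cho_solve((c, low), diff.T)
            maha = np.einsum("ij,ji->i", diff, y)
            logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
            out[rows, s] = -0.5 * (len(idx) * LOG_2PI + logdet + maha)
    return out


def forward_backward_from_log_emissions(log_e: np.ndarray,
                                        transition: np.ndarray) -> ForwardBackwardTable:
    """Forward/backward tables from explicit log emissions and transitions.

    Start is uniform: F_1(s) = e_1(s)/m, B_n(s) = 1.  Sum recursions give
    the evidence and posteriors; the same recursions with max in place of
    sum give the tables used by MAP decoding.
    """
    log_e = np.asarray(log_e, dtype=float)
    n, m = log_e.shape
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.asarray(transition, dtype=float))
    log_start = -np.log(m)

    lf = np.empty((n, m))
    lmf = np.empty((n, m))
    lf[0] = log_start + log_e[0]
    lmf[0] = lf[0]
    for i in range(1, n):
        trans = lf[i - 1][:, None] + log_pi  # (r, s)
        lf[i] = logsumexp(trans, axis=0) + log_e[i]
        lmf[i] = np.max(lmf[i - 1][:, None] + log_pi, axis=0) + log_e[i]

    lb = np.empty((n, m))
    lmb = np.empty((n, m))
    lb[n - 1] = 0.0
    lmb[n - 1] = 0.0
    for i in range(n - 2, -1, -1):
        term = log_pi + log_e[i + 1][None, :] + lb[i + 1][None, :]
        lb[i] = logsumexp(term, axis=1)
        lmb[i] = np.max(log_pi + log_e[i + 1][None, :] + lmb[i + 1][None, :], axis=1)

    log_evidence = float(logsumexp(lf[n - 1]))
    if not np.isfinite(log_evidence):
        raise EncodingFailure("zero likelihood under every letter path")
    return ForwardBackwardTable(
        log_forward=lf,
        log_backward=lb,
        log_max_forward=lmf,
        log_max_backward=lmb,
        log_evidence=log_evidence,
    )


def forward_backward(series: FragmentSeries | MultiChainFragmentSeries,
                     a: StructuralAlphabet) -> ForwardBackwardTable:
    """Forward/backward inference for a fragment series under an alphabet."""
    return forward_backward_from_log_emissions(emission_log_matrix(series, a), a.transition)


def posterior(t: ForwardBackwardTable) -> np.ndarray:
    """Marginal posterior POST[i, s] = P(S_i = s | X); rows sum to 1."""
    return np.exp(t.log_forward + t.log_backward - t.log_evidence)


def entropy_neff(post_row: np.ndarray) -> tuple[float, float]:
    """Entropy (nats) and effective letter count of one posterior row.

    0 log 0 is treated as 0; ENT lies in [0, log m] and NEFF = exp(ENT) in
    [1, m].
    """
    p = np.asarray(post_row, dtype=float)
    nz = p > 0
    ent = float(-np.sum(p[nz] * np.log(p[nz])))
    ent = max(ent, 0.0)
    return ent, float(np.exp(ent))


def map_decode(t: ForwardBackwardTable) -> np.ndarray:
    """MAP letter indices: per-position argmax of max-forward + max-backward.

    The resulting sequence attains the maximal joint density P(X, S) over
    all paths.  Ties break to the lowest letter index, deterministically.
    """
    score = t.log_max_forward + t.log_max_backward
    return np.argmax(score, axis=1)


def map_joint_log_score(t: ForwardBackwardTable) -> float:
    """Log joint density P(X, MAP) of the decoded path."""
    return float(np.max(t.log_max_forward[-1]))


def encode(series: FragmentSeries | MultiChainFragmentSeries,
           a: StructuralAlphabet) -> EncodingResult:
    """Full encoding: MAP sequence, POST matrix, ENT/NEFF, log evidence.

    A k-chain consensus input yields one shared letter sequence for all
    chains; with k = 1 the result is identical to single-chain encoding.
    """
    table = forward_backward(series, a)
    post = posterior(table)
    ent_neff = np.array([entropy_neff(row) for row in post])
    idx = map_decode(table)
    return EncodingResult(
        map_sequence=[a.letters[s].code for s in idx],
        map_indices=idx,
        post=post,
        ent=ent_neff[:, 0],
        neff=ent_neff[:, 1],
        log_evidence=table.log_evidence,
    )


def write_encoding(result: EncodingResult, a: StructuralAlphabet, prefix,
                   legacy: bool = False) -> dict[str, str]:
    """Write MAP / POST / ENT-NEFF files for one encoding.

    ``<prefix>.map.txt`` holds whitespace-separated letter codes on one
    line (or the concatenated legacy single-character rendering with
    ``legacy=True``); ``<prefix>.post.csv`` one row per fragment with the
    letter codes as header; ``<prefix>.neff.csv`` fragment, ENT (nats),
    NEFF columns.  Returns the written paths.
    """
    import pandas as pd
    from .alphabet import legacy_code_map

    prefix = str(prefix)
    paths = {}
    if legacy:
        cmap = legacy_code_map(a)
        map_text = "".join(cmap[c] for c in result.map_sequence)
    else:
        map_text = " ".join(result.map_sequence)
    paths["map"] = prefix + ".map.txt"
    with open(paths["map"], "w") as fh:
        fh.write(map_text + "\n")

    paths["post"] = prefix + ".post.csv"
    pd.DataFrame(result.post, columns=a.codes,
                 index=pd.RangeIndex(1, result.n + 1, name="fragment")).to_csv(paths["post"])

    paths["neff"] = prefix + ".neff.csv"
    pd.DataFrame(
        {"ent_nats": result.ent, "neff": result.neff},
        index=pd.RangeIndex(1, result.n + 1, name="fragment"),
    ).to_csv(paths["neff"])
    return paths
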