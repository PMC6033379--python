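"""Synthetic alphabets, descriptor data, 3D fixtures, and brute-force oracles.

Everything here is seeded and deterministic.  Synthetic descriptor series
are emitted directly in descriptor space (the descriptor map from 3D is not
bijective, so no inverse-geometry reconstruction is attempted); separate 3D
fixtures (ideal helices, extended strands, random-walk coils) exercise the
geometry and I/O path.  The brute-force encoder enumerates every hidden
path and is the independent oracle for the forward/backward engine.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alphabet import StructuralAlphabet, StructuralLetter
from .descriptors import FragmentSeries
from .engine import MultiChainFragmentSeries, emission_log_matrix
from .structure import CAlphaTrace


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic encoding problem.

    mean_separation controls the typical distance between letter means in
    descriptor space (angstroms); noise_scale the emission covariance
    magnitude.  Large separation relative to noise makes decoding
    near-perfect; comparable magnitudes make it ambiguous.
    """

    m: int = 3
    n: int = 8
    k: int = 1
    seed: int = 0
    mean_separation: float = 4.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 1 or self.k < 1:
            raise ValueError("need m >= 2, n >= 1, k >= 1")
        if self.mean_separation <= 0 or self.noise_scale <= 0:
            raise ValueError("mean_separation and noise_scale must be positive")


def random_alphabet(spec: SyntheticSpec) -> StructuralAlphabet:
    """Random valid alphabet: separated Gaussian letters, random stochastic pi.

    Means are drawn on a sphere of radius ``mean_separation`` (plus jitter),
    covariances as A A^T + eps I with eps = 1e-3 * noise_scale so they are
    positive definite by construction.  Classes cycle helix/coil/strand so
    class-level statistics are exercised too.
    """
    rng = np.random.default_rng(spec.seed)
    letters = []
    classes = ("helix", "coil", "strand")
    for s in range(spec.m):
        direction = rng.normal(size=4)
        direction /= np.linalg.norm(direction)
        mu = direction * spec.mean_separation + rng.normal(scale=0.1 * spec.mean_separation, size=4)
        A = rng.normal(scale=np.sqrt(spec.noise_scale / 4.0), size=(4, 4))
        sigma = A @ A.T + 1e-3 * spec.noise_scale * np.eye(4)
        cls = classes[s % 3]
        prefix = {"helix": "A", "coil": "C", "strand": "B"}[cls]
        letters.append(
            StructuralLetter(
                code=f"{prefix}{s + 1}",
                legacy_code=chr(ord("A") + s) if s < 26 else f"#{s}",
                sl_class=cls,
                frequency=1.0 / spec.m,
                mu=mu,
                sigma=sigma,
            )
        )
    raw = rng.uniform(0.1, 1.0, size=(spec.m, spec.m))
    transition = raw / raw.sum(axis=1, keepdims=True)
    return StructuralAlphabet(letters=letters, transition=transition)


def sample_chain(a: StructuralAlphabet, n: int, k: int = 1,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[np.ndarray, MultiChainFragmentSeries]:
    """Sample one hidden path and k replicate descriptor chains from it.

    The path starts uniform and follows the alphabet's transition matrix;
    every chain emits independently from the path letter's Gaussian, with
    full availability.  Returns (hidden path indices, multi-chain series).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = a.m
    path = np.empty(n, dtype=int)
    path[0] = rng.integers(m)
    for i in range(1, n):
        path[i] = rng.choice(m, p=a.transition[path[i - 1]])
    chains = []
    for _ in range(k):
        values = np.empty((n, 4))
        for i, s in enumerate(path):
            values[i] = rng.multivariate_normal(a.letters[s].mu, a.letters[s].sigma)
        chains.append(FragmentSeries.from_values(values))
    return path, MultiChainFragmentSeries(per_chain=chains)


def mask_fragments(series: FragmentSeries, drops: dict[int, frozenset],
                   ) -> FragmentSeries:
    """Copy of a series with some fragments' availability J replaced.

    ``drops`` maps fragment index to its new availability set (a subset of
    the old one); values outside the new J are blanked.
    """
    values = series.values.copy()
    available = list(series.available)
    for i, newJ in drops.items():
        newJ = frozenset(newJ)
        if not newJ <= available[i]:
            raise ValueError(f"fragment {i}: new J must be a subset of the old one")
        available[i] = newJ
        for d in range(1, 5):
            if d not in newJ:
                values[i, d - 1] = np.nan
    return FragmentSeries(values=values, available=available,
                          source_labels=series.source_labels)


MAX_ENUMERATION = 10**6


def brute_force_encode(series: FragmentSeries | MultiChainFragmentSeries,
                       a: StructuralAlphabet
                       ) -> tuple[float, np.ndarray, tuple[int, ...], float]:
    """Exact enumeration over all m^n hidden paths.

    Returns (evidence, POST matrix, best path, best path probability), all
    on the probability (not log) scale.  The independent oracle for the
    forward/backward engine; refuses instances with more than 10^6 paths.
    """
    log_e = emission_log_matrix(series, a)
    n, m = log_e.shape
    if m ** n > MAX_ENUMERATION:
        raise ValueError(f"{m}^{n} paths exceed the enumeration limit")
    pi = a.transition
    evidence = 0.0
    post = np.zeros((n, m))
    best_path: tuple[int, ...] | None = None
    best_p = -np.inf
    for path in itertools.product(range(m), repeat=n):
        logp = -np.log(m) + log_e[0, path[0]]
        for i in range(1, n):
            logp += np.log(pi[path[i - 1], path[i]]) + log_e[i, path[i]]
        p = np.exp(logp)
        evidence += p
        for i, s in enumerate(path):
            post[i, s] += p
        if p > best_p:
            best_p = p
            best_path = path
    post /= evidence
    return evidence, post, best_path, best_p


# ---------------------------------------------------------------------------
# 3D geometry fixtures


def helix_fixture(n_res: int, chain_id: str = "A",
                  rise: float = 1.5, radius: float = 2.3,
                  twist_deg: float = 100.0) -> CAlphaTrace:
    """Ideal alpha-helical C-alpha spiral.

    Defaults are the canonical alpha-helix parameters: 1.5 A rise and 100
    degree twist per residue on a 2.3 A radius.  By the screw symmetry all
    fragments of the trace have identical descriptor 4-vectors.
    """
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    t = np.deg2rad(twist_deg) * np.arange(n_res)
    coords = np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n_res)])
    return CAlphaTrace(
        chain_id=chain_id,
        residue_labels=[(i + 1, "") for i in range(n_res)],
        coords=[c for c in coords],
        present=np.ones(n_res, dtype=bool),
    )


def strand_fixture(n_res: int, chain_id: str = "A") -> CAlphaTrace:
    """Extended beta-strand-like zigzag with 3.8 A C-alpha virtual bonds."""
    if n_res < 4:
        raise ValueError("need at least 4 residues")
    step = 3.3
    amp = np.sqrt(3.8**2 - step**2) / 2.0
    coords = np.column_stack([
        step * np.arange(n_res),
        amp * np.where(np.arange(n_res) % 2 == 0, 1.0, -1.0),
        np.zeros(n_res),
    ])
    return CAlphaTrace(
        chain_id=chain_id,
        residue_labels=[(i + 1, "") for i in range(n_res)],
        coords=[c for c in coords],
        present=np.ones(n_res, dtype=bool),
    )


def mirror_trace(t: CAlphaTrace) -> CAlphaTrace:
    """Mirror image (z -> -z) of a trace; flips only the sign of X4."""
    coords = [None if c is None else c * np.array([1.0, 1.0, -1.0]) for c in t.coords]
    return CAlphaTrace(chain_id=t.chain_id, residue_labels=list(t.residue_labels),
                       coords=coords, present=t.present.copy())


def random_backbone(n_res: int, seed: int | np.random.Generator = 0,
                    chain_id: str = "A", segment_len: tuple[int, int] = (6, 14),
                    noise: float = 0.15) -> CAlphaTrace:
    """Synthetic mixed backbone: helix / strand / coil segments plus noise.

    Segments of random length alternate among the three geometry classes,
    each continuing from the previous endpoint; coordinates get isotropic
    Gaussian noise of scale ``noise`` (angstroms).  Purely a geometric
    emulation of secondary-structure variety — no Ramachandran realism.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    pos = np.zeros(3)
    while len(pts) < n_res:
        length = int(rng.integers(segment_len[0], segment_len[1] + 1))
        kind = rng.integers(3)
        if kind == 0:
            seg = helix_fixture(max(length, 4)).coord_array()
        elif kind == 1:
            seg = strand_fixture(max(length, 4)).coord_array()
        else:  # coil: random walk, 3.8 A steps
            steps = rng.normal(size=(max(length, 4), 3))
            steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
            seg = np.cumsum(steps, axis=0)
        # random rotation, then continue from the current endpoint
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        seg = (seg - seg[0]) @ q.T + pos
        if pts:
            # keep a plausible virtual bond into the new segment
            direction = seg[1] - seg[0] if len(seg) > 1 else rng.normal(size=3)
            direction = direction / max(np.linalg.norm(direction), 1e-9)
            seg = seg + 3.8 * direction
        pts.extend(seg)
        pos = pts[-1]
    coords = np.array(pts[:n_res]) + rng.normal(scale=noise, size=(n_res, 3))
    return CAlphaTrace(
        chain_id=chain_id,
        residue_labels=[(i + 1, "") for i in range(n_res)],
        coords=[c for c in coords],
        present=np.ones(n_res, dtype=bool),
    )


def geometry_alphabet(seed: int = 0, samples: int = 400,
                      noise: float = 0.25) -> StructuralAlphabet:
    """3-letter alphabet (helix A1 / strand B1 / coil C1) fit to 3D fixtures.

    Letter Gaussians are the empirical mean and covariance of descriptors
    computed from noisy helix, strand and random-coil fragments, so the
    alphabet is consistent with what :func:`random_backbone` generates.
    Transitions favour staying in the same letter (0.9 self-transition),
    mimicking the persistence of secondary-structure elements.
    """
    from .descriptors import trace_to_fragments

    rng = np.random.default_rng(seed)
    pools = {"helix": [], "strand": [], "coil": []}
    for _ in range(max(samples // 40, 4)):
        for kind, base in (("helix", helix_fixture(14)), ("strand", strand_fixture(14))):
            arr = base.coord_array() + rng.normal(scale=noise, size=(14, 3))
            tr = CAlphaTrace(chain_id="A", residue_labels=base.residue_labels,
                             coords=[c for c in arr], present=np.ones(14, dtype=bool))
            pools[kind].append(trace_to_fragments(tr).values)
        steps = rng.normal(size=(14, 3))
        steps = 3.8 * steps / np.linalg.norm(steps, axis=1, keepdims=True)
        arr = np.cumsum(steps, axis=0) + rng.normal(scale=noise, size=(14, 3))
        tr = CAlphaTrace(chain_id="A", residue_labels=[(i + 1, "") for i in range(14)],
                         coords=[c for c in arr], present=np.ones(14, dtype=bool))
        pools["coil"].append(trace_to_fragments(tr).values)

    letters = []
    for code, legacy, cls in (("A1", "A", "helix"), ("B1", "M", "strand"), ("C1", "B", "coil")):
        X = np.vstack(pools[cls])
        mu = X.mean(axis=0)
        sigma = np.cov(X.T) + 1e-4 * np.eye(4)
        letters.append(StructuralLetter(code=code, legacy_code=legacy, sl_class=cls,
                                        frequency=1 / 3, mu=mu, sigma=sigma))
    transition = np.full((3, 3), 0.05)
    np.fill_diagonal(transition, 0.9)
    return StructuralAlphabet(letters=letters, transition=transition)
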