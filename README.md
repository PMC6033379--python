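# saflex

Structural-alphabet encoding of protein Cα backbones by exact hidden-Markov
inference — with per-position uncertainty, rigorous missing-residue handling,
and consensus encodings for homomeric replicate chains.

## The problem

A structural alphabet compresses a protein's 3D backbone into a 1D sequence
over a small set of prototype local conformations ("structural letters"),
so that 3D structures can be analysed and compared with ordinary sequence
tools.  This package implements the encoding side of a 27-letter alphabet
in which each letter is a 4-dimensional Gaussian over fragment descriptors
and letters follow a Markov chain.  It is aimed at structural
bioinformaticians who want, beyond a single best letter sequence, a
quantitative account of *how certain* that encoding is — per position — and
who routinely face PDB files with missing residues or with several copies
of the same chain.

## The model

A fragment is four consecutive Cα atoms; a chain of `n_res` residues gives
`n = n_res − 3` overlapping fragments.  Fragment *i* is described by
`X_i = (X_i1, …, X_i4)`:

- `X_i1 = |Cα_i − Cα_{i+2}|`, `X_i2 = |Cα_i − Cα_{i+3}|`,
  `X_i3 = |Cα_{i+1} − Cα_{i+3}|` (Å),
- `X_i4 = η·|Cα_{i+3} − H|`, the out-of-plane distance of the last atom
  from the plane of the first three, signed by local handedness
  (mirror reflection flips only this sign).

The hidden letters `S_1:n ∈ {1..m}` form a Markov chain with uniform start
`1/m` and transition matrix `π`; each letter `s` emits
`X_i ~ N(μ_s, Σ_s)`.  The joint density is

```
P(X_1:n, S_1:n) = (1/m) ∏ π(S_{i−1}, S_i) ∏ e_i(S_i),
e_i(s) = N(X_i; μ_s, Σ_s)
```

Forward/backward recursions (in log space, with log-sum-exp) give

- **MAP** — the jointly most probable letter sequence (max-forward /
  max-backward recursions),
- **POST** — the marginal posterior `P(S_i = s | X_1:n)` at every position,
- **ENT/NEFF** — the posterior entropy and its exponential, the *effective
  number of letters* at each position (1 = certain, m = maximally
  uncertain).

**Missing residues.**  When Cα atoms are absent, each fragment keeps the
subset `J ⊆ {1,2,3,4}` of descriptors whose atoms survive, and the emission
becomes the exact Gaussian marginal `N(X_i[J]; μ_s[J], Σ_s[J,J])`; a fully
missing fragment emits density 1 and is carried by the Markov context
alone.

**Homomer consensus.**  `k` replicate chains aligned on one residue index
can share a single hidden path; the emission is then the product of the
per-chain (possibly restricted) Gaussian densities.  The consensus encodes
the complete protein even when individual chains have large missing
regions, and is systematically sharper than any single-chain encoding.

## The packaged alphabet

`src/saflex/data/saflex27_synthetic.json` carries the published 27-letter
nomenclature — 4 helix letters (A1–A4), 18 coil letters (C1–C18), 5 strand
letters (B1–B5), their legacy single-character codes and training
frequencies — but **synthetic** Gaussian and transition parameters (the
authentic numeric tables are not machine-readable here; the file name says
so).  Any alphabet in the same JSON format, including the authentic
parameters once sourced, loads through `saflex.load_alphabet`.

## Worked example

```
$ python - <<'EOF'
from saflex import write_calpha_pdb
from saflex.synthetic import random_backbone
write_calpha_pdb(random_backbone(52, seed=12), "demo.pdb")
EOF
$ saflex encode demo.pdb --chain A --out demo
encoded A: 49 fragments -> demo.*
$ head -c 130 demo.map.txt
A2 A2 A2 A2 A2 A2 A2 A2 C6 B5 C4 A3 A2 A2 A2 A2 A2 A2 A2 A2 A2 C15 C11 C9 C10 C10 C7 C8 C6 C13 C1 C13 C14 C10 C5 C4 A2 A2 A2
$ head -3 demo.neff.csv
fragment,ent_nats,neff
1,1.0886341854327997,2.9702145386242784
2,1.2035779741552095,3.33201749254816
$ cat demo.log
chain A: n_res=52 n_fragments=49 fragments_with_reduced_J=0
log_evidence=-234.568441
```

The 52-residue synthetic backbone yields 49 fragments.  The MAP reads as
runs of helix letters (`A2`) broken by coil stretches and one strand-like
fragment — the generator built this chain from helix/strand/coil segments.
`demo.neff.csv` shows ~3 effective letters at the chain start (the first
fragment has no left context), and `demo.post.csv` holds the full 49×27
posterior matrix.  `saflex consensus file.pdb --chains A,B,C,D` produces
the same three outputs for a shared hidden path, and `saflex experiment`
runs the seeded residue-masking protocol (`--manifest` takes lines of
`pdb_path chain`; `src/saflex/data/pdb39_ids.txt` lists the 39 PDB entries
of the published protocol for users with network access).

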