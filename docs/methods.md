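# Methods

## Dynamic models

Expression is modeled in discrete time, one step per (pseudo-)time point.
For protein `i` with PPI partners `j`, coding gene `g_i`:

```
p_i(t+1) = p_i(t) + Σ_j α_ij p_i(t) p_j(t) − σ_i p_i(t) + λ_i g_i(t) + β_i + ε
```

with translation rate `λ_i ≥ 0` and degradation `σ_i ≥ 0`. For a
gene-type node `k` (mRNA, miRNA gene or lncRNA gene) with candidate TFs
`i`, miRNAs `r` and lncRNAs `z`:

```
g_k(t+1) = g_k(t) + Σ_i a_ki p_i(t) − Σ_r b_kr g_k(t) m_r(t)
           + Σ_z c_kz o_z(t) − μ_k g_k(t) + δ_k + ω
```

with repression `b_kr ≥ 0` and degradation `μ_k ≥ 0`. The basal levels
`β, δ` absorb unmodeled regulation and epigenetic effects; large
between-stage basal shifts are flagged (`sysid.flag_epigenetic`).

## Constrained least squares

Each node yields a one-step-ahead regression `y = Ψ θ + e` whose columns
are, for proteins, `[p_j p_i …, g_i, p_i, 1]` with
`θ = [α…, λ, 1−σ, β]`, and for gene-type nodes
`[p_i …, g_k m_r …, o_z …, g_k, 1]` with `θ = [a…, −b…, c…, 1−μ, δ]`.
The sign constraints are axis-aligned (one component per inequality), so
the inequality system `A θ ≤ b` reduces to box constraints, solved with
the deterministic bounded-variable least-squares routine
`scipy.optimize.lsq_linear(method="bvls")`. The general `(A, b)` view is
retained on `RegressionProblem.constraints`; solutions are feasible to
1e−9 and satisfy the KKT conditions (verified against an oracle in the
test suite). Rank-deficient designs are solved with a warning; the
estimate is then one least-squares minimizer, not unique.

## AIC order detection

False candidate edges are pruned by minimizing

```
AIC = log(RSS / T) + penalty / T      (natural log, RSS floored at 1e−12)
```

with penalty `2K` for proteins (`K` retained PPI partners) and, as
published, `2I + R + L` for gene-type nodes over retained TFs, miRNAs
and lncRNAs; a `penalty_mode="standard"` switch gives the conventional
`2(I + R + L)`. The default search fits the full candidate model once,
ranks regulators by estimated-ability magnitude, refits the nested
sequence of top-`k` subsets and keeps the AIC minimum (ties toward fewer
regulators). An `exhaustive=True` oracle enumerates all subsets; the
nested search matches it on ≥ 95 % of random instances with ≤ 10
candidate regulators.

Note on pure-noise behavior: with the `2K/T` penalty a spurious
regulator survives whenever its RSS improvement (asymptotically χ²(1))
exceeds 2, so on pure-noise responses the retained set is sparse but not
almost-always empty (measured ≈ 0.4 empty rate, < 1 retained regulator
on average over 200 seeds). A near-always-empty result would require a
BIC-like `log T` penalty, which this method deliberately does not use.

## Principal network projection

The system matrix `H` stacks one row per node (proteins, genes, miRNA
genes, lncRNA genes) and one column per regulator (proteins, miRNAs,
lncRNAs), holding the identified abilities. From the SVD `H = U D Vᵀ`,
the eigen-expression fraction of direction `h` is `E_h = d_h² / Σ d²`;
`γ` is the smallest rank whose cumulative energy reaches 0.85. Each
node's projection value is `DR(w) = ‖H_w,· V[:, :γ]‖₂`, computed for all
rows including gene rows. The core network is the subnetwork induced by
the top-`n` nodes by `DR` (default 4000; ties broken lexicographically).
With full energy the projection degenerates to plain row 2-norms.

## DTI network

Feature vectors concatenate drug (363) and protein-target (996)
descriptors (1359 total). Training pairs are balanced by down-sampling
unknown pairs to match the known interactions. Features are
standardized (zero-variance columns floored with a warning) and
PCA-reduced to 1000 components (or the data's rank if smaller), then fed
to a feed-forward network — ReLU hidden layers 512/256/128/64 with
per-layer inverted dropout 0.5/0.4/0.3/0.1, a sigmoid output, binary
cross-entropy loss and Adam (lr 0.003) — implemented directly on numpy
(no deep-learning framework dependency). Data split 70/30
train+validation/test with 10 % of all pairs as validation; early
stopping (patience 10) restores the best validation state.

## Drug design

Biomarkers are differential core-network nodes intersected with an
aging-gene list and a druggable-target list, keeping only nodes whose
later-stage mean expression differs by more than 5 % (relative) from the
earlier stage, with the direction recorded. Candidate drugs ranked by
DTI probability then pass:

1. **Regulation reversal** — a (drug, biomarker) pairing survives only
   if the drug's recorded regulation sign opposes the biomarker's
   abnormal direction; pairings without a record are dropped.
2. **Sensitivity** — drugs with |cell-viability effect score| > τ
   (default 0.3) are removed as cytotoxic/proliferative.

Surviving drugs are combined by greedy set cover (largest uncovered-
biomarker gain, ties by mean DTI probability then drug id) into a
multiple-molecule drug; biomarkers no drug can cover are reported.

## Synthetic generator scope

`gwgen.simulate` draws a typed ground-truth network (Bernoulli edge
densities per kind), dynamic parameters from configurable uniform
ranges, and iterates the exact model equations with i.i.d. Gaussian
process noise. Interaction strengths are rescaled (×0.7, up to 40
rounds) until noise-free trajectories from two initial states stay
bounded, so generated systems are simulable at any configured horizon.
`contaminate_candidate` injects a kind-proportional quota of random
false edges, returning the truth mask for scoring.
`gwgen.fixtures` plants a low-rank bilinear interaction rule for DTI
training data and explicit regulation/sensitivity annotations for
drug-design tests. These generators exist to make every stage scoreable
against known truth; they are not calibrated to any real tissue.

## Numerical choices and limitations

- All randomness flows from explicit seeds via
  `numpy.random.default_rng`; per-module seeds derive from a master seed
  with `SeedSequence` (`pipeline.module_seed`).
- Dense SVD (`numpy.linalg.svd`) is used throughout; system matrices at
  desk scale are small. Very large networks would need sparse/truncated
  decompositions.
- The published headline numbers for real skin-aging data depend on
  external databases and microarray series and are out of scope; all
  quantitative claims here are on synthetic benchmarks with planted
  ground truth.
- Stage splitting allows overlapping age ranges and requires ≥ 4 samples
  per stage for cubic-spline interpolation.
- The identification assumes the candidate network is a superset of the
  truth; edges absent from the candidate can never be recovered.
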