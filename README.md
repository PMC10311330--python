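# reconboost

Iterative gene-weight boosting for single-cell manifold reconstruction.

## The problem

Single-cell RNA-seq dissociates tissue, so the spatial (or temporal)
context of each cell is lost. Reconstruction algorithms — autoencoders,
optimal-transport embedders such as novoSpaRc-style methods — can recover a
low-dimensional cell manifold from expression alone, but only if the input
genes actually vary along that manifold. In practice the input mixes genes
driven by different structures (space, circadian time, unrelated programs)
plus noise, and the uninformative genes degrade the reconstruction. Marker
panels solve this when they exist; `reconboost` is for when they don't.

## The method

Keep a probability distribution `p` over the `n` genes, starting uniform
(`p₀ = uₙ`). Each round:

1. fit the baseline reconstructor on the reweighted matrix `diag(pₜ) X`;
2. measure the per-gene reconstruction error `mₜ[g]`;
3. multiplicative-weights update `pₜ₊₁[g] ∝ pₜ[g]·exp(−η·mₜ[g])` — the
   closed-form minimiser of `η⟨mₜ, p⟩ + D(p, pₜ)` where
   `D(p,q) = Σᵢ pᵢ ln(pᵢ/qᵢ)`;
4. project onto the capped simplex `Πₙ^c = {p : ‖p‖∞ ≤ c}` with
   `c = 1/(ε·|S|)`, so no single gene dominates.

Genes the baseline reconstructs well gain weight; after ~10 rounds `p`
concentrates on the manifold-informative subset `S`, the baseline — now fed
an input dominated by `S` — reconstructs the manifold better, and
thresholding the final weights at `(1−δ)/n` (default `δ = 0.2`) recovers
`S` itself. The baseline is a black box: a shallow tanh autoencoder and a
simplified entropic Gromov–Wasserstein spatial embedder are built in, and
any external tool can be plugged in through an adapter.

The package also ships the synthetic single-cell benchmark generator used
to validate the method (latent manifolds `Unif([0,1])^d` / `N(0, I_d)`,
random polynomial gene programs of degree ≤ 3, two-block mixtures D1–D4,
unit-variance-preserving Gaussian noise at scale β) and the evaluation
suite (relative-entropy traces, AUC, TPR/FPR, mutual information,
mean-profile correlations, linear zonation labelling).

## Worked example

Simulate a two-manifold mixture (recipe D3: 30 genes on `Unif([0,1])²`
stacked with 30 genes on `Unif([0,1])`, degree-3 programs, noise β = 0.25),
run 10 boosting rounds with the autoencoder baseline, and score the
recovered gene set against the ground truth:

```sh
reconboost simulate --recipe D3 --genes 30 --cells 2000 --beta 0.25 \
    --seed 7 --out demo/sim
reconboost run --matrix demo/sim/matrix.mtx --baseline ae --rounds 10 \
    --eta 1.0 --epsilon 0.5 --s-size 30 --seed 7 --out demo/traj
reconboost evaluate --traj demo/traj --truth demo/sim/genes.tsv \
    --out demo/report.json
```

The run logs one line per round (abridged):

```
round 0   loss=0.000231277  entropy=0.0000  top: g59=0.0167, g58=0.0167, ...
round 5   loss=0.000184796  entropy=0.0176  top: g15=0.0297, g20=0.0294, ...
round 10  loss=0.000131136  entropy=0.0478  top: g44=0.0280, g34=0.0276, ...
```

and `evaluate` prints:

```
{"auc": 1.0, "tpr": 0.9666666666666667, "fpr": 0.0}
```

Reading: the weighted reconstruction loss falls by ~43% over 10 rounds
while the weights drift away from uniform (`entropy` is `D(pₜ, uₙ)`); the
final weights rank every 1-D-manifold gene above every 2-D-manifold gene
(AUC 1.0), and thresholding at `(1−0.2)/60` recovers 29 of the 30
ground-truth genes with no false positives.

The same pipeline is available as a library:

```python
from reconboost import (AutoencoderSpec, ReweightConfig, classify_genes,
                        fit_autoencoder, make_benchmark, run_reweighting)

ds = make_benchmark("D3", n_genes_per_block=30, N=2000, beta=0.25, seed=7)
cfg = ReweightConfig(eta=1.0, epsilon=0.5, s_size=30, max_rounds=10, seed=7)
traj = run_reweighting(
    ds.X,
    lambda Xw, t, s: fit_autoencoder(Xw, AutoencoderSpec(code_dim=1, seed=s)),
    cfg,
)
informative = classify_genes(traj.final_weights, delta=0.2)
```

## Layout

| module | contents |
| --- | --- |
| `reconboost.simplex_core` | gene-weight distributions, relative entropy, MWU step, capped-simplex KL projection, threshold classification |
| `reconboost.losses` | expression-matrix container, weighted MSE and per-gene gradients, spatial variance loss |
| `reconboost.baselines` | autoencoder, entropic-GW spatial embedder, external-tool adapter |
| `reconboost.driver` | the alternate-minimisation loop, termination, trajectories |
| `reconboost.simulator` | manifolds, polynomial gene programs, mixtures D1–D4, noise model |
| `reconboost.evaluation` | entropy traces, AUC, TPR/FPR, mutual information, profile correlation, zonation labels |
| `reconboost.io_cli` | Matrix Market / CSV / TSV I/O, standardization, manifests, the `reconboost` CLI |

See `docs/methods.md` for the model, the defaults and their rationale, and
known limitations.
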