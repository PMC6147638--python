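# freqlayer

Frequency-based multiplex and full-multilayer functional networks from
multichannel oscillatory time series, and spectral analysis of their
combinatorial supra-Laplacians.

The package covers the full workflow:

- **`freqlayer.synthetic_signals`** — MEG-like multichannel signal generator
  with planted intra-band and cross-band (amplitude–amplitude) coupling and
  optional theta-phase/gamma-amplitude modulation, so the empirical pipeline
  is testable end-to-end without any recordings.
- **`freqlayer.coordination`** — zero-phase band-pass filtering (theta
  [3–8], alpha [8–12], beta [12–30], gamma [30–100] Hz), histogram mutual
  information between every pair of node-layer series, block-permutation
  surrogate thresholding (default block length 1018 samples), and linear
  normalization into [0, 1]; the result is sliced into layer blocks and
  interlayer coupling blocks of a supra-network.
- **`freqlayer.netmodels`** — Erdős–Rényi and Barabási–Albert layers,
  homogeneous/heterogeneous diagonal couplings, all-to-all couplings, random
  interlayer-edge deletion, and multiplex→multilayer densification.
- **`freqlayer.spectral`** — supra-adjacency assembly, weighted
  combinatorial Laplacians, algebraic connectivity λ2, λ2/λ3 scans over the
  interlayer weight p, transition-point detection (crossing onset with
  bisection refinement; gap minimum with a no-crossing flag for avoided
  crossings), and the closed-form small-p/large-p reference curves.
- **`freqlayer.experiments`** — ensemble sweeps (interlayer-weight
  heterogeneity, missing interlayer edges, densification) from YAML configs
  with tidy-table outputs, and per-subject summary statistics of the four
  network representations (unfiltered, aggregated, multiplex, multilayer).

## CLI

```sh
# generate synthetic signals (YAML config: n_channels, n_samples, bands,
# coupling pair lists, noise_sd, ...)
freqlayer simulate-signals --config signals.yaml --out signals --seed 1

# build the frequency-based supra-network from signals
freqlayer build-network --signals signals --bands theta,alpha,beta,gamma \
    --block-length 1018 --bins sqrt --seed 1 --out net [--multiplex]

# synthetic network realizations and spectral scans
freqlayer make-ensemble --model er --n 250 --pcon 0.052 --coupling diagonal \
    --seed 1 --out ens
freqlayer spectral-scan --net ens --p-min 0.3 --p-max 20 --n-p 40 --out scan.tsv

# ensemble sweeps and summaries
freqlayer sweep --config sweep.yaml --kind heterogeneity --out outdir
freqlayer summarize --nets ens --out summary.json
```

Signals are stored as TSV (rows = channels) plus a JSON sidecar; networks as
a dense TSV supra-adjacency matrix, a JSON header (layer names/sizes, node
ordering) and a tab-separated edge list. All generators and the pipeline are
seed-deterministic.

## Notes on fidelity choices

- The printed bin-count rule `5*round(t/10)` is implemented verbatim
  (`coordination.default_bin_count`) but is impractically large at realistic
  series lengths; the pipeline default is the `sqrt`-scaled variant, and the
  rule actually used is recorded in the output metadata.
- The combinatorial Laplacian uses the weighted form `L = diag(s) − M`
  throughout, which reduces to the unit-weight form for binary graphs.
- Surrogate permutations are drawn independently per channel by default; a
  shared-permutation mode is available (`MIConfig.same_permutation`).
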