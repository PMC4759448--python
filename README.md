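# meristo

Meristograms for acanthocephalan systematics — and, more generally, for
any organism whose serially homologous structures vary smoothly along an
axis.

Thorny-headed worms (Acanthocephala) attach to the host gut with a
proboscis armed with longitudinal rows of hooks whose size and shape vary
with position along the row.  A **meristogram** turns one pooled
collection of hook rows into four standardized curves over
percent-position *p = i·100/(n+1)*:

- **L** — blade length,
- **B** — base width,
- **A** — estimated cross-sectional area, *L·B/2*,
- **R** — robustness ratio, *B·100/L*,

each first expressed as a percentage of its own row maximum (which removes
absolute size, and with it sexual size dimorphism), then smoothed by a
moving average of width *w* percent sliding in 1 % steps, optionally
resampled onto the integer position grid by linear interpolation, and
finally rescaled so each curve's maximum is 100.  The shapes of the
curves and the loops formed by their intersections are taxonomic
characters; a minimum admissible window, ⌈100/(n_min+1)⌉ with n_min the
shortest row's hook count, guarantees every specimen contributes to every
curve segment.

The package also provides:

- validation of the triangular area formula by OLS of estimated on
  digitized area (`meristo.areacheck`);
- a comparison layer — feature matrix over the common position grid,
  covariance PCA, and UPGMA dendrograms under Euclidean, Manhattan,
  maximum and Minkowski distances with Newick export (`meristo.compare`);
- a synthetic-data generator with known positional trends so the whole
  pipeline is testable end to end (`meristo.synth`);
- a command-line interface with plotting (`meristo.cli`, `meristo.viz`).

## Worked example

Simulate two single-sex samples and compute their pooled meristogram:

```sh
$ meristo simulate --seed 1 --out female.csv
wrote 12 rows / 119 hooks to female.csv (generator seed=1)
$ meristo simulate --seed 2 --out male.csv
wrote 12 rows / 126 hooks to male.csv (generator seed=2)
$ meristo meristogram female.csv:female male.csv:male \
    --label demo --mai auto --out demo_meristogram.csv --plot demo.png
demo: MAI 12%, peaks L=34%, B=60%, A=43%, R=74%
```

`--mai auto` resolved the window to this collection's minimum admissible
interval, 12 % (the shortest simulated row has 8 hooks: ⌈100/9⌉ = 12).
The peak line reports where each curve attains its maximum of 100: the
longest hooks sit about a third of the way from the distal tip (L = 34 %),
the broadest bases and largest areas near the middle (B = 60 %, A = 43 %),
and the stoutest hooks in the proximal third (R = 74 %) — the generator's
default trends place the length peak at relative position 0.35 and the
base peak at 0.6, so the pipeline has recovered them to within about one
position unit.  The CSV holds the four curves at integer positions:

```
position,L,B,A,R
10,59.2546,61.4972,42.7558,60.9945
11,61.524,61.6038,44.5611,59.0786
...
```

Comparing several collections (here three simulated taxa) prints the
variance captured by the first two principal components and one Newick
dendrogram per distance metric:

```sh
$ meristo compare "alpha=taxon0.csv" "beta=taxon1.csv" "gamma=taxon2.csv" \
    --mai 17 --out-dir cmp
PC1+PC2 variance fraction: 1.000
euclidean: (beta:7.964597733,(alpha:6.937075701,gamma:6.937075701):1.027522033);
...
```

(With only three collections two components necessarily carry all the
variance.)  `meristo validate-area table.csv --species A` prints the
fitted line `estimated = a x measured + b (R^2 = ..., n = ...)`, and
`meristo dimorphism f.csv:female m.csv:male` renders per-sex panels at the
MMAI, 1.5× and 2× MMAI.

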