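# ecpred

Is the top-level EC (Enzyme Commission) class of an enzyme-catalysed
reaction predictable from its *mechanism*, or only from the *overall
chemical transformation*?  `ecpred` is a benchmark pipeline for that
question, built around MACiE-style reaction records: each entry carries a
four-level EC code, the participating species, the overall set of bond
changes from substrates to products, and the stepwise mechanism as one
bond-change set per elementary step.

## The method

Bond changes use the `X.Y_a.b` token grammar — a bond between elements X
and Y changing order from *a* to *b* (0 = absent), so `C.N_0.1` is C–N
single-bond formation.  Five descriptor encodings are compared:

1. **overall bond change** — token counts of the overall transformation;
2. **composite bond change** — token counts summed over every mechanism
   step, so a transient bond (formed in one step, broken later) registers
   as both formation and cleavage;
3. **human designed** — 28 engineered features of the overall reaction
   (e.g. `f:X-H`, bonds to hydrogen formed; `dv:C`, total change in bond
   order to carbon; `water.OH-.su`, water as substrate; `Mod_Diff`,
   weight difference between largest substrate and product — zero for
   isomerisations);
4. **overall reaction similarity** — count-vector Tanimoto
   T(a,b) = Σ min(aₜ,bₜ) / (Σ aₜ + Σ bₜ − Σ min(aₜ,bₜ)) of overall
   bond-change vectors against every reference entry;
5. **mechanistic similarity** — global Needleman–Wunsch alignment of step
   sequences (step-vs-step Tanimoto as match score, score normalised by
   the longer mechanism), taking the better of the two reaction
   directions.

Classifiers (SVM-RBF, SVM-polynomial, kNN, Random Forest) are tuned by
internal grid search and evaluated by 10-fold cross-validation with a
strict protocol: similarity columns belonging to held-out entries are
deleted before training, and count/engineered features are z-scaled with
training-fold statistics only.  Performance is summarised by accuracy and
Gorodkin's K-category correlation R_K (the multi-class Matthews
coefficient):

    R_K = (N·c − Σₖ tₖpₖ) / √((N² − Σₖ pₖ²)(N² − Σₖ tₖ²))

with N predictions, trace c, row sums tₖ and column sums pₖ of the 6×6
confusion matrix.  Classifier pairs are compared with an exact fold-wise
permutation test: all 2¹⁰ = 1024 sign assignments of the per-fold
differences in correct predictions are enumerated and the observed sum
D₀ ranked among them (p = n/1024, n ≥ 2 always).

A synthetic data generator produces MACiE-like corpora with realistic
class proportions, class-dependent bond-change signatures, species
rosters that trigger the engineered features, and a *mechanism
heterogeneity* knob h controlling whether same-class entries share
mechanism templates — the lever behind the central scientific contrast.

## Worked example

```python
from ecpred import (GeneratorConfig, generate_dataset, build_benchmark_matrix,
                    cross_validate, ClassifierSpec, permutation_test)

entries = generate_dataset(GeneratorConfig(n_entries=320, seed=42))
labels = [e.ec_class for e in entries]
spec = ClassifierSpec("rf", {"mtry": ["sqrt"], "n_trees": [200]})

results = {}
for kind in ("overall-bond", "composite-bond"):
    matrix = build_benchmark_matrix(entries, kind)
    results[kind] = cross_validate(matrix, labels, spec, n_folds=10, seed=42)
    r = results[kind]
    print(f"{kind:15s} accuracy {r.accuracy:.3f}  R_K {r.rk:.3f}")

test = permutation_test(results["overall-bond"].fold_outcome,
                        results["composite-bond"].fold_outcome)
print(f"D_0 = {test.d0}, p = {test.p:.4f} ({test.n}/1024 permutations)")
```

prints

```
overall-bond    accuracy 0.975  R_K 0.969
composite-bond  accuracy 0.891  R_K 0.863
D_0 = 27, p = 0.0078 (8/1024 permutations)
```

At the generator's default mechanism heterogeneity (h = 0.8) the overall
transformation descriptors beat the mechanistic (composite) encoding by a
margin the permutation test calls significant: the overall classifier got
27 more predictions right across the ten folds, and only 8 of the 1024
sign permutations are that extreme.  Setting h = 0 (fully conserved
within-class mechanisms) makes the gap vanish — the package's synthetic
restatement of the finding that similar reactions tend to proceed by
dissimilar mechanisms.

The same machinery is exposed on the command line:

```sh
ecpred generate --n 320 --heterogeneity 0.8 --seed 42 --out entries.json
ecpred benchmark --entries entries.json --descriptor overall-bond \
                 --classifier rf --folds 10 --seed 42 --out report_a.json
ecpred compare --report-a report_a.json --report-b report_b.json
ecpred split-external --train base.json --new additions.json --out split.json
```

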