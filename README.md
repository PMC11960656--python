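# phylocure

Bayesian phylogenetic survival-cure modeling of under-detected binary
traits, built around a case study design: how many parrot species use
tools, given that absence of evidence is not evidence of absence?

Species that have never been observed performing a behavior are
ambiguous — they may lack the capacity, or may simply be under-studied.
`phylocure` resolves this with a split-population ("cure") survival
model on two right-censored detection channels: time-to-first-detection
runs on a *research effort* clock (papers published; video-platform
search hits), so a species with huge effort and no detection is probably
a true non-user, while a never-studied species stays uncertain. The
probability of being a non-user follows a logistic regression on feeding
strategy and relative brain size (encephalization quotient, EQ), plus a
phylogenetic random effect with an Ornstein–Uhlenbeck kernel on
patristic distances, so capacity can cluster on the tree. The package
also measures phylogenetic signal in the observed codings (Pagel's λ for
binary traits) and reconstructs ancestral states under the liability
threshold model.

Everything runs offline on synthetic data from the package's own
generator; the model, the algorithms, and the validation machinery are
the deliverable. See `docs/methods.md` for the mathematical details.

## Layout

- `src/phylocure/` — the library:
  - `data` — species records, EQ, effort coding, evidence merging, CSV I/O
  - `phylo` — trees, patristic distances, Yule simulation, MRCAs
  - `model` — cure-mixture likelihood, OU kernel, joint log-density
  - `inference` — gradient-free MCMC (elliptical slice + slice-within-Gibbs
    with ASIS interweaving), pooling over tree ensembles, summaries
  - `signal` — Pagel's λ by ML for binary traits (pruning algorithm)
  - `asr` — threshold-model ancestral state reconstruction (Gibbs)
  - `simulate` — the synthetic-data generator with stored ground truth
  - `validate` — AUC, leave-one-species-out CV, parameter recovery
  - `report` — headline estimands assembled into one report
- `analysis/` — numbered narrative drivers (simulate → fit → signal →
  ancestral states → validation → report), writing under `results/`
- `scripts/acceptance.py` — seeded end-to-end run writing a JSON of the
  principal quantities
- `tests/` — oracle-based unit/property tests plus `test_acceptance.py`

## Worked example

Simulate a 100-species study under the default conditions and fit the
model (this is `analysis/01` + `analysis/02` in miniature):

```python
from phylocure.simulate import SimConfig, generate_dataset
from phylocure.inference import FitConfig, sample_posterior, rank_species, sum_undetected

dataset, ensemble, truth = generate_dataset(SimConfig(n_species=100, n_trees=5), seed=20240)
draws = sample_posterior(dataset, ensemble,
                         FitConfig(n_warmup=1000, n_samples=1000), seed=20241)
print(rank_species(draws).head(3))
print({k: round(v, 2) for k, v in sum_undetected(draws).items() if k != "draws"})
```

On this seed the generator yields 63 species with evidence (31
literature, 47 video) out of 100, with true EQ slope 1.1 on the tool-use
scale. The fit (about 90 s) ranks species by posterior median tool-use
probability:

```
species   median     q025      q25      q75     q975  evidence
Sp 0079 0.817873 0.503947 0.728182 0.886276 0.961748      True
Sp 0073 0.807121 0.449781 0.709451 0.882268 0.967965      True
Sp 0094 0.799038 0.449248 0.705687 0.874082 0.968153      True
```

and the assembled report (`analysis/06`) gives:

```
expected undetected tool users: 19.10 [14.48, 23.03]
implied prevalence range: 77.5% - 86.0%
EQ slope (tool-use scale): 0.68 [0.11, 1.34]        (truth 1.1)
generalist - specialist (tool-use scale): -0.25 [-1.14, 0.62]   (truth 0.3)
```

Ancestral reconstruction at the root of the same trees (`analysis/04`,
threshold model, pooled over 3 trees) gives a root tool-use probability
of 0.32 under the literature-only coding, 0.63 under the union coding,
and 0.54 when the cure model's posterior probabilities are used as soft
tip states. Pagel's λ for the evidence codings (`analysis/03`) is
estimated at 0 on most trees — with the default kernel decay (ρ² = 5)
the latent trait's correlation dies off quickly, so the binary evidence
carries little recoverable signal; this is expected behavior, not a
failure of the machinery (which recovers λ with MAE ≈ 0.05–0.11 when
signal exists; see the acceptance suite).

Validation on the same dataset (`analysis/05`) gives a classification
AUC of 0.77 for posterior medians against the evidence labels, and
leave-one-species-out cross-validation recovers 55 of 63 held-out users
within the range of the other users' medians. Two honest caveats from
the recovery study (10 replicates at the study conditions): the kernel
decay ρ² is only weakly identified (its posterior shrinks toward the
prior, 90% coverage ≈ 0.5), and with 63% of species evidence-positive
the users' median range is wide, so the LOO baseline rate is high
(0.81) — the LOO check mostly guards against gross misranking here.

## Reproduction

```sh
python analysis/01_simulate_dataset.py          # results/data/
python analysis/02_fit_model.py --warmup 1000 --samples 1000   # results/fit/
python analysis/03_phylogenetic_signal.py       # results/signal/
python analysis/04_ancestral_states.py          # results/asr/
python analysis/05_validation.py                # results/validation/ (~20 min)
python analysis/06_report.py                    # results/report.json
```

or run the seeded end-to-end acceptance computation (~3 min):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which records, among others: `classification_auc` 0.81,
`undetected_count_median` 17.3 [11.5, 22.7], `lambda_recovery_mae`
0.048, `asr_two_tip_oracle_error` 0.0028, `likelihood_oracle_error`
< 1e-12 (values for `--seed 1`).

All randomness is controlled by explicit integer seeds; rerunning any
command with the same seed reproduces its outputs bit for bit.

## Testing philosophy

Every numerical claim is tested against an *independent* oracle: closed
forms, `scipy` quadrature and distributions, Monte Carlo with standard
errors, matrix exponentials (vs the pruning algorithm), exhaustive
enumeration (likelihoods summing to 1 over all tip-state assignments;
pair-counting AUC), exact Gaussian orthant probabilities (threshold-model
ASR), grid-search dominance for optimizers, and simulate-and-refit
coverage for the sampler. `tests/test_acceptance.py` re-verifies the
eight headline guarantees end to end.

Convergence caveat: the OU variance η² is weakly identified by
binary-like data and mixes slowest; short runs can emit an R-hat warning
for it. The warning is informative, not fatal — increase
`n_warmup`/`n_samples` for final runs.
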