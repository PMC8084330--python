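# pempni

Prediction of binding-affinity changes (ΔΔG) caused by missense mutations in
protein–DNA and protein–RNA complexes (the two mutation classes are called
MPDs and MPRs), with geometric-partition energy features, interface-based
structural features and weighted random-forest ensembles.

## Who this is for

Structural bioinformaticians who have (a) wild-type and mutant complex
structures in PDB format, (b) per-residue-pair MM/GBSA energy-decomposition
tables produced by an external energy engine (or by the built-in synthetic
generator), (c) PSI-BLAST conservation profiles, and (d) a mutation table,
and who want per-mutation ΔΔG estimates (kcal·mol⁻¹) plus the probability
that a mutation significantly decreases binding affinity
(ΔΔG ≥ 1 kcal·mol⁻¹).

## The model

A binding free energy decomposed at the residue-pair level gives five terms
per monomer pair: ΔG ≈ ΔE_ele + ΔE_vdw + ΔG_GB + ΔG_SA. These are aggregated
into five energy feature groups:

* **EWC** — energies of the whole complex;
* **ETOR** — energies between the mutated (target) residue and other protein
  residues, partitioned by distance shell: 0 Å (the self term), 0–3, 3–4,
  4–5, 5–6 and >6 Å;
* **EPP** — per-residue energy sums over the same shells;
* **EINI** — pair-energy sums over the interface vs the rest, where the
  interface is every residue–nucleotide pair with a heavy-atom distance
  < 5 Å;
* **EPI** — the interface sum split into residue–residue,
  residue–nucleotide and nucleotide–nucleotide pairs.

Seventeen nonenergy groups cover solvent accessibilities (bound/unbound/
difference, absolute and relative, five atom categories, plus cumulative
interface sums), hydrogen bonds, contact strengths, seven knowledge-based
scores from a pluggable provider, and Jensen–Shannon-divergence
conservation. Each group carries wild-type values and mutant − wild-type
differences.

Random forests are fitted per feature group; groups are chosen by
sequential backward selection on the leave-one-complex-out (LOCOV) Pearson
correlation; and the final score combines the models as

    MPD:  Energy = α·ETOR + (1−α)·EPI        (α = 0.4)
    MPR:  Energy = EWC
    both: Score  = β·Energy + (1−β)·Nonenergy (β = 0.6 MPD, 0.5 MPR)

with α and β searched on an 11-point grid over [0, 1] when requested.

## Worked example

Everything below runs from synthetic data — the generator plants a linear
ΔΔG signal in the whole-complex energy change, so the pipeline's recovery
of that signal is checkable:

```sh
pempni simulate --seed 17 --n-complexes 3 --mutations-per-complex 2 --outdir run/bundle
pempni features --bundle-dir run/bundle --outdir run/feat
pempni train    --features-dir run/feat --mutation-class MPD --n-estimators 40 --outdir run/model
pempni evaluate --features-dir run/feat --mutation-class MPD --n-estimators 40 --outdir run/eval
pempni predict  --features-dir run/feat --bundle run/model/model.joblib --outdir run/pred
```

`run/eval/report.json` then contains the pooled LOCOV metrics, e.g.

```json
"regression": {"metrics": {
    "ETOR":      {"PCC": 0.633, "RMSE": 1.508},
    "EPI":       {"PCC": 0.871, "RMSE": 1.054},
    "energy":    {"PCC": 0.839, "RMSE": 1.190},
    "nonenergy": {"PCC": -0.244, "RMSE": 2.298},
    "pempni":    {"PCC": 0.565, "RMSE": 1.579}}}
```

(PCC = Pearson correlation between pooled out-of-fold predictions and the
labels; RMSE in kcal·mol⁻¹; `energy` is the α-weighted ETOR/EPI
combination and `pempni` the β-weighted final ensemble.) With only six
mutations the energy models already track the planted signal while the
nonenergy model sees mostly noise — at the benchmark scale of
`scripts/acceptance.py` the ensemble reaches PCC ≈ 0.89. A line of
`run/pred/predictions.tsv`:

```
SYN000:A:1:P>H    -0.254    0.199
```

is one mutation's `ddg_pred` (kcal·mol⁻¹) and `hotspot_prob` (probability
of ΔΔG ≥ 1 kcal·mol⁻¹).

## Package layout

| module                       | contents                                             |
|------------------------------|------------------------------------------------------|
| `pempni.structure_io`        | PDB reading, chain typing, interfaces, Levy classes, mutation records |
| `pempni.energy_features`     | decomposition-table reader, EWC/ETOR/EPP/EINI/EPI    |
| `pempni.nonenergy_features`  | SASA, H-bonds, contacts, conservation, ENDES slot    |
| `pempni.modeling`            | forests, LOCOV, backward selection, ensembles, metrics |
| `pempni.comparison`          | grouped ΔΔG summaries, Δd distance, binding modes, rank tests |
| `pempni.synthetic_fixtures`  | toy complexes, planted-signal tables, profiles, datasets |
| `pempni.cli_config`          | configuration and the `pempni` command-line interface |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
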