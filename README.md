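# intermit

Model-free characterization of **intermittent gene transcription** from
single-cell RNA-seq count matrices.

Many genes appear in only a small fraction of the cells of a tissue. Two
very different pictures can produce that observation: the gene may be
expressed *continuously but only in a rare, specialized cell type*
(cellular differentiation, "case A"), or it may be *transcribed
intermittently in most cells*, switching on and off slowly compared with
the mRNA lifetime (temporal intermittency, "case B"). `intermit`
implements a two-parameter description of every gene that is agnostic
about the mechanism behind the count fluctuations, together with the
correlation-based test that discriminates the two pictures, and a
synthetic-data generator that produces both situations with known ground
truth so the whole analysis is testable end to end.

## The statistics

For gene *i* in tissue *k*, from the counts *M<sub>ijk</sub>* over the
*N<sub>k</sub>* cells, compute the population moments
μ<sub>ik</sub> and σ²<sub>ik</sub>, then

- **activation probability** p<sub>ik</sub> = μ²<sub>ik</sub>/σ²<sub>ik</sub>
- **peak activity** α<sub>ik</sub> = σ²<sub>ik</sub>/μ<sub>ik</sub>
- log forms: **activity** A = ln α and **intermittency** I = −ln p.

Under a two-point on/off model (a cell carries α transcripts with
probability p, else none), μ = αp and σ² = p(1−p)α², so these ratios
recover p/(1−p) and α(1−p) — i.e. p and α themselves when p ≪ 1. A gene
with I > ln 5 (active in fewer than one cell in five) is classified as
*intermittent*; ERCC spike-in sequences, present in every cell at a fixed
concentration, calibrate the I ≈ 0 ideal.

The discriminator between the two pictures is the pairwise statistic

K<sub>ii′,k</sub> = C<sub>ii′,k</sub>·σ<sub>i</sub>σ<sub>i′</sub>/(μ<sub>i</sub>μ<sub>i′</sub>) = ⟨M<sub>i</sub>M<sub>i′</sub>⟩/(μ<sub>i</sub>μ<sub>i′</sub>) − 1,

where C is the Pearson-type correlation of the two genes' counts. If two
genes are never expressed in the same cell, ⟨M<sub>i</sub>M<sub>i′</sub>⟩ = 0
and K = −1 *exactly*; under intermittency with shared activation
programs, the significantly correlated pairs are overwhelmingly positive
instead. The package also quantifies how the parameters behave across
tissues — per-gene averages Ā, Ī, deviations ΔA, ΔI, and their pooled
variances with a 20×20 (ΔI, ΔA) histogram — and fits the power-law tail
of the activity distribution: an exponential tail exp(−mĀ) in the log
variable is exactly a power law P(α) ~ α^−(m+1).

The two-state (telegraph) promoter model is included as theory: its
stationary moments (Peccoud–Ycart), exact Poisson–Beta sampling, and the
regime (p₀ ≪ 1, k_deg ≫ k_on+k_off) in which the model-free (p, α) read
off the kinetic parameters (p₀, M₀).

## Worked example

Generate two tissues of 600 cells with 40 intermittent genes whose peak
activity α is shared between tissues while the activation probability p
varies, then run the full pipeline:

```python
from intermit import synthetic, pipeline

specs = synthetic.random_intermittent_specs(
    40, ["heart", "liver"], seed=1, p_low=0.05, p_high=0.5, n_programs=8)
adata, truth = synthetic.gen_intermittent_counts(
    specs, {"heart": 600, "liver": 600}, cell_size_dispersion=0.3, seed=1)

cfg = pipeline.AnalysisConfig(protocol="facs", seed=1, max_pairs=10_000)
summary = pipeline.run_analysis(cfg, adata)
```

Printed summary (abridged):

```
"var_dA": 0.0108,  "var_dI": 0.357,
"fraction_K_near_minus1": 0.0096,
"positive_fraction_significant": 0.985,
"intermittent_fraction_by_tissue": {"heart": 0.375, "liver": 0.625},
"verdict": "intermittency-consistent"
```

Read: the activity dispersion across tissues (0.011) is ~30× smaller than
the intermittency dispersion (0.357) — activity persists, intermittency is
what tissues modulate; almost no gene pair shows the K ≈ −1 exclusivity
signature while 98.5% of the significantly correlated pairs are positive,
so the correlation structure points at temporal intermittency rather than
rare cell types, matching how the data were generated.

The same pipeline is available from the shell:

```sh
intermit simulate --case intermittent --n-genes 40 --n-cells 600 \
    --tissues heart,liver --seed 1 --out sim/
intermit run-all --in sim/ --out results/
```

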