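# dmbc — Dirichlet-multinomial Bayes classification of microbial compositions

`dmbc` is a two-class Bayes classifier for microbiome count tables: given
16S rRNA taxon- or OTU-abundance read counts for healthy and diseased
samples, it fits a Dirichlet-multinomial (DM) distribution per class,
selects a small set of *signature taxa* by cross-validated AUC, and scores
new samples with a Bayes posterior that can incorporate known disease
prevalence. It is aimed at researchers who have a labelled count table from
mothur/QIIME-style processing and want a probabilistic diagnosis plus an
interpretable list of discriminating taxa.

## The model

A sample is a count vector **s** = (s₁, …, s_T) over T taxa with
N = Σ_t s_t total reads. Within a class, taxon proportions vary between
samples, so counts are overdispersed relative to a multinomial; the DM
distribution models this by compounding a Dirichlet over proportions with
multinomial sampling:

    P(s | α) = N! / ∏_t s_t! · Γ(A)/Γ(A+N) · ∏_t Γ(α_t + s_t)/Γ(α_t),
    A = Σ_t α_t

parameterized by the expected composition π_t = α_t/A and the
overdispersion θ = 1/(1+A) (θ → 0 recovers the multinomial). Per-class
parameters (π̂, θ̂) are estimated by maximum likelihood. Classification of
a sample M uses Bayes' rule,

    Pr(C | M) = Pr(M | C) Pr(C) / Σᵢ Pr(M | Cᵢ) Pr(Cᵢ),

with the class prior Pr(C) either the empirical class frequency of the
training set or a user-supplied prevalence.

Because T is often large (thousands of OTUs) and n small, the classifier
first ranks taxa by a two-sided Mann-Whitney U test between classes, then
iterates k = 1, 2, …: keep the top-k taxa individually, merge all others
into one "other" column (preserving each sample's read depth — no
rarefaction), and record the leave-one-out cross-validated AUC of the
diseased-class posterior. The k with the highest AUC (smallest k on ties)
defines the signature taxa, and the final DM parameters are refitted on the
full training data reduced to those columns.

## Worked example

The package ships a deterministic 6-sample toy table
(`dmbc.make_toy_table()`):

```
sample_id  label     Bacteroides  Prevotella  Faecalibacterium  Ruminococcus
H001       healthy   30           5           10                5
H002       healthy   15           12          15                8
H003       healthy   40           3           5                 2
D001       diseased  5            25          10                10
D002       diseased  10           40          5                 5
D003       diseased  3            20          15                12
```

```bash
python -c "from dmbc import make_toy_table, write_table; write_table(make_toy_table(), 'toy.tsv')"
dmbc train toy.tsv --out toy --positive-label diseased
# best_k=1 loocv_auc=0.8889 signature_taxa=Bacteroides
```

The selection trace (`toy.trace.tsv`) shows each round:

```
k  auc                 taxa
1  0.8888888888888888  Bacteroides
2  0.6666666666666666  Bacteroides,Prevotella
3  0.6666666666666666  Bacteroides,Prevotella,Ruminococcus
```

Keeping *Bacteroides* alone (one column for it, one merging the other three
taxa) gives the best held-out ranking of diseased over healthy samples
(AUC 0.889 — with 3 samples per class there are 9 diseased–healthy pairs,
and one held-out sample scores on the wrong side). Scoring the training table with the
fitted model:

```bash
dmbc predict toy.tsv --model toy.model.json --out preds.tsv
```

```
sample_id  p_healthy              p_diseased             call
H001       0.9999999999994085     5.918032169693921e-13  healthy
H002       0.9785148370706896     0.021485162929310162   healthy
H003       1.0                    2.3366643174050843e-23 healthy
D001       0.016176988566285373   0.9838230114337148     diseased
D002       0.08002056872097839    0.9199794312790214     diseased
D003       0.01140346498990256    0.9885965350100973     diseased
```

All six samples are called correctly; the fitted compositions over
(*Bacteroides*, other) are π̂ = (0.57, 0.43) for healthy versus
(0.11, 0.89) for diseased. `dmbc simulate` writes synthetic two-class DM
tables with known ground truth, and `dmbc eval` reports the leave-one-out
AUC of a table or an existing model; `--prior 0.2,0.8` supplies a disease
prevalence in place of the empirical class frequencies.

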