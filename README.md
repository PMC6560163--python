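# mycsig

Tools for scoring MYC transcriptional activity in pancreatic ductal
adenocarcinoma (PDAC) organoid cohorts from NanoString-style count data, and
for analysing BET-inhibitor (BETi) drug screens on those organoids.

PDAC tumors with high c-MYC activity respond preferentially to BET
bromodomain inhibitors such as JQ1 and NHWD-870, which suppress MYC
transcription.  `mycsig` implements the 16-gene expression score used to
split patient-derived organoids into **MYC-high** and **MYC-low** subgroups,
the chemogram analysis (dose–response fitting, IC50, total AUC, subgroup
comparison) used to test whether that split predicts BETi sensitivity, and
the concordance analysis between patient-derived xenografts (PDTX) and their
matched organoids.  A synthetic-data generator with known ground truth backs
the whole pipeline with end-to-end tests.

## The score

Sixteen MYC target transcripts are measured per sample: ten induced by MYC
(*CAD, CCT4, CDC20, KPNA2, MAD2L1, MCM2, PLK1, RFC4, RUVBL2, SRM*) and six
repressed (*BCL2L15, CTSE, ERN2, RAB25, TXNIP, VSIG2*), alongside
housekeeping references (*SDHA, CLTC, TBP, GUSB, RPL19*).  For a cohort of
samples $j = 1..n$:

1. each signature gene $g$ is rescaled so that $\sum_j x_{gj} = 100$
   (cohort-relative normalization);
2. for each sample, every (up, down) gene pair yields a ratio
   $r = x_{\text{up},j} / x_{\text{down},j}$ — 60 ratios in total;
3. the sample's **score** is the median of its 60 ratios;
4. score > 1 → **MYC-high**, otherwise **MYC-low**.

Because each gene is normalized by its cohort sum, the score is invariant to
per-gene scale (probe efficiency) but is relative to the cohort being
analysed.

Chemograms fit viability against dose with the four-parameter log-logistic
model $v(d) = b + (t - b) / (1 + (d/\mathrm{IC}_{50})^h)$ by robust
(soft-L1) least squares, and summarize sensitivity as the total AUC — the
trapezoidal area of mean viability vs $\log_{10}$ dose (lower AUC = more
sensitive).  MYC-high vs MYC-low AUC distributions are compared by
Mann–Whitney U (Welch t alongside).

## Worked example

Simulate a 24-organoid cohort (11 truly MYC-high, 13 MYC-low, two-fold
signature effect, negative-binomial counts), then score it:

```sh
mycsig simulate cohort --seed 11 --out demo
mycsig score --counts demo/counts.tsv --normalize-housekeeping --out demo/scores.tsv
```

The score command prints the subgroup summary:

```
   label  n  percent
MYC-high 11     45.8
 MYC-low 13     54.2
```

and `demo/scores.tsv` starts:

```
sample	score	label	n_ratios
P05	2.561580821	MYC-high	60
P01	2.498357048	MYC-high	60
P08	2.38181467	MYC-high	60
```

All 11 simulated MYC-high organoids score above 1 (here 45.8% / 54.2% of the
cohort), and each score is the median of 60 up/down ratios.  The full
pipeline — cohort, scoring, JQ1 + NHWD-870 chemograms, subgroup AUC
comparison — runs with one command:

```sh
mycsig run --seed 11 --out demo_run
```

`demo_run/group_comparisons.json` then reports, for the simulated screen in
which MYC-high organoids are 100× more BETi-sensitive (IC50 0.1 vs 10 µM):

```
JQ1:  mean AUC  MYC-high 213.2  vs  MYC-low 369.3   (Mann-Whitney p = 3.9e-05)
cross-drug AUC correlation (JQ1 vs NHWD-870): r = 0.998
```

i.e. the scored subgroups separate cleanly in drug sensitivity, in the
direction the signature predicts, and responses to the two BET inhibitors
correlate strongly across samples.

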