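# imgwas — classification-based GWAS for image phenotypes

`imgwas` runs genome-wide association scans on whole brain-image slices by
turning association testing into a classification problem. Instead of
regressing a scalar imaging trait (an iQT/IDP) on genotype, each SNP's
genotypes *label* the images: under a dominant model, subjects with the
homozygous wild-type genotype AA form one class and carriers (Aa or aa) the
other. A small CNN is trained to tell the two classes of images apart; if
the images are classifiable beyond chance, the SNP is a candidate for
association with brain structure. The package is aimed at imaging-genetics
researchers who want to scan high-dimensional phenotypes — full image
frames, where mean-based univariate tests on single pixels miss textural
and non-linear effects — without hand-crafting summary statistics.

## Model

For subject *i* with image **X**ᵢ and genotype *G*ᵢⱼ at SNP *j*, the
working assumption is

```
Xᵢ ~ Eⱼ   if Gᵢⱼ = AA
Xᵢ ~ Fⱼ   if Gᵢⱼ = Aa or aa,
```

with the null hypothesis *E*ⱼ = *F*ⱼ (no association). The scan decides
between the two by training a classifier per (SNP, plane) task on a
subject-grouped 7:1:2 train/validation/test split and scoring the held-out
test set with two imbalance-robust metrics:

- **MCC** = (tp·tn − fp·fn) / √((tp+fp)(tp+fn)(tn+fp)(tn+fn)) ∈ [−1, 1];
  random guessing gives ≈ 0, perfect prediction 1.
- **macro F1**: the unweighted mean of the per-class F1 scores over both
  label designations.

Significance of a top-ranked task is assessed by a *fine-tuning* test: the
classifier is retrained 20× on the true labels and 20× on permuted subject
labels, and the two samples of metric values are compared with a one-sided
Welch t-test.

Components: genotype I/O (VCF/TSV) and GWAS QC (call rate ≥ 95 %, exact
Hardy-Weinberg p ≥ 1e−6, MAF ≥ 5 %, autosomes only); middle-slice
extraction from registered NIfTI volumes in the axial, coronal and sagittal
planes with per-image [0, 1] normalization; the reference CNN (three 3×3
conv blocks with 8/16/32 filters and 2×2 max pooling, dense-128, dropout
0.5, softmax head; Adam, lr 1e−4, ≤ 30 epochs, early stopping with patience
10) plus a fast ridge-on-pixels classifier for large scans; Grad-CAM++
class saliency maps; a univariate simulation comparing t-test p-values with
decision-tree classification metrics; and a synthetic cohort generator with
planted causal variants for validation.

## Worked example

Generate a synthetic cohort of 120 subjects and 40 SNPs (32×32 slices,
HWE genotypes) with one planted causal variant, scan it, rank SNPs and test
the top hit:

```bash
imgwas make-cohort --out demo --n-subjects 120 --n-snps 40 \
    --image-size 32 --causal snp00007:1.0 --seed 42
# cohort: 120 subjects, 40 SNPs, 296 scans -> demo

imgwas scan --genotypes demo/genotypes.tsv --images demo/slices \
    --out demo/scan.tsv --seed 42
# scanned 120 (SNP, plane) tasks; 120 scored; mean MCC 0.0274

imgwas rank --scan demo/scan.tsv --k 5 --out demo/rank
imgwas finetune --genotypes demo/genotypes.tsv --images demo/slices \
    --snp snp00007 --plane axial --reps 10 --out demo/ft.tsv --seed 42
# mcc: t = 10.435, one-sided p = 1.254e-06
# macro_f1: t = 10.863, one-sided p = 8.949e-07
```

The scan's mean MCC over all tasks sits near 0 — most SNPs have no planted
effect, so their genotype-labeled images are not classifiable and their
test MCC fluctuates around chance. The planted variant `snp00007` scores
MCC 1.0 in all three planes, tops the ranking, and its fine-tuning test
separates real retrains from permuted retrains at p ≈ 1e−6: the task is
classifiable beyond chance. `imgwas overlap` reports the three-set Venn
counts of the per-plane top lists, and `imgwas saliency` trains the CNN on
one SNP and writes per-class Grad-CAM++ maps and their absolute difference,
which highlights the image region driving the classification.

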