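# cytoscreen

Two-step screening of cervical cytology images: detect atypical cell
clusters, then grade each one on the Bethesda severity scale with an ordinal
label-smoothing loss.

## The problem

Cervical cytology screening must find atypical squamous cells in images full
of crowded, overlapping cell clusters, and grade them on the ordinal Bethesda
scale

```
NILM < ASC-US < LSIL < ASC-H < HSIL < SCC
```

Two properties make this different from generic image classification:

1. **Normality is the absence of findings.** A detector trained only on the
   five atypical classes returns nothing on a normal image; the image is then
   called NILM. Normal cells never need to be annotated.
2. **Severity is ordinal.** Disease progression is continuous, so a cluster
   near a class boundary genuinely resembles its ordinal neighbours. Calling
   an HSIL "ASC-H" is a far smaller error than calling it "NILM", and the
   training loss should know that.

`cytoscreen` implements this workflow end to end at desk scale: a
deterministic nuclear-density blob detector and a trainable multinomial
logistic classifier stand in for the heavyweight CNN detectors/classifiers
used at clinical scale, behind backend contracts that any detector or
classifier can satisfy. A seeded synthetic scene generator supplies annotated
crowded-cluster images with six ordinal severity classes, so every stage is
testable with no clinical data.

## The ordinal label-smoothing loss

For `c` classes and true class `k ∈ [1, c]`, the one-hot target is replaced by

```
y_i = n^(−|k−i|),   i = 1..c,   n ≥ 1 integer
```

so the true class keeps weight exactly 1 and the weight decays geometrically
with ordinal distance (for `n = 2` and `k = 4`:
`(0.125, 0.25, 0.5, 1, 0.5, 0.25)`). The cross-entropy

```
L = − Σ_i y_i log ŷ_i
```

then evaluates every term instead of only the true class, rewarding
probability mass placed on classes adjacent to the truth. With a one-hot
target it reduces to `−log ŷ_k`. The smoothed vector may optionally be
renormalized to a distribution (`normalized=True`); the default keeps the
literal weights.

Other components: a 36× offline oversampling scheme (a nine-filter
photometric bank crossed with the four flip states, box annotations remapped
under flips), online scale augmentation and random erasing for classifier
training, PASCAL-style detection mAP, per-class/macro screening metrics, and
an ordinal cutoff recall for the binary triage question.

## Worked example

The package ships two reference confusion matrices from a published
two-stage screening evaluation (stage 1 = detection, stage 2 =
classification; rows are true classes, columns predicted). Evaluating the
stage-2 matrix:

```
$ cytoscreen evaluate --stage 2
         accuracy  precision  recall  f_measure
NILM         98.0       92.3    92.3       92.3
ASC-US       87.8       60.0    41.4       49.0
LSIL         92.2       76.2    59.3       66.7
ASC-H        91.7       66.7    90.3       76.7
HSIL         85.4       57.9    61.1       59.5
SCC          88.3       77.6    80.4       78.9
Average      90.6       71.8    70.8       70.5
```

Each row is one Bethesda class scored one-vs-rest; the `Average` row is the
unweighted macro mean. NILM is the best-classified class (F = 92.3%) — which
matters most, because stage 1 deliberately over-detects and stage 2 must
recognize the normal clusters that slip through. On the stage-1 matrix the
binary screen at the ASC-US cutoff is perfect:

```
$ cytoscreen evaluate --stage 1 --cutoff ASC-US
...
cutoff >= ASC-US recall: 100.0%
```

i.e. nothing truly at or above ASC-US is ever called NILM by the detector —
the property a triage stage must have.

The loss in action:

```python
>>> import numpy as np
>>> from cytoscreen import smooth_label, one_hot, cross_entropy
>>> np.asarray(smooth_label(k=4, c=6, n=2))
array([0.125, 0.25 , 0.5  , 1.   , 0.5  , 0.25 ])
>>> p = np.array([0.05, 0.05, 0.15, 0.55, 0.15, 0.05])
>>> round(cross_entropy(one_hot(4), p), 4)      # only the true class counts
0.5978
>>> round(cross_entropy(smooth_label(k=4, c=6, n=2), p), 4)
4.3673
```

Other subcommands: `synth` (generate an annotated synthetic dataset),
`augment` (36× expansion of a directory), `fit` (train the ordinal
classifier), `run` (two-step pipeline over a manifest, emitting per-stage
confusion matrices), `evaluate-detections` (mAP).

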