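# marrowsect

Unsupervised section classification for free-text bone marrow reports.

Hematopathology reports are built from named sections — specimen received,
clinical information, peripheral blood smear, bone marrow aspirate,
aspirate differential, iron content, bone marrow biopsy, comment,
diagnosis, disclaimer — and knowing which section a block of text came
from is the first step toward completeness checking, structured storage,
and bootstrapping labeled corpora for heavier NLP models. `marrowsect`
implements a lightweight classical pipeline that learns this assignment
without supervision, for pathology informaticians who need labeled marrow
text but not a GPU.

## Model

A report is split at its section header lines and the headers are
removed. Each resulting text block *d* is mapped to a binary feature
vector

> x_i(d) = 1 if vocabulary n-gram g_i occurs in d, else 0, i = 1..V

over the V = 200 most frequent n-grams of the training text, after
accession numbers, CD markers and numeric values are collapsed to the
placeholder tokens `ACCNUM`, `CDNUM`, `NUM`. K-means with k = 10
centroids (one per section) is run 10 times with random centroid
initialization and the run minimizing

> SSE = Σ_d ‖x(d) − c(d)‖²

is kept; each cluster is assigned the section most common among its
training blocks, and purity (modal-section fraction of a cluster) and
accuracy (correct predictions / all predictions) measure the result. A
two-stage ensemble re-classifies the blocks of the least pure cluster
with a second 5-centroid K-means over three structural features: number
of numeric tokens, median paragraph length, and the block's relative
position in its report. The train/test split is chronological (oldest
80% train), so evaluation always measures transfer to newer reports.

Because real marrow corpora cannot leave hospital systems, the package
includes a seeded generator of structurally realistic synthetic reports
(`marrowsect.synthetic`) with known section labels; see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
import marrowsect as ms

corpus = ms.generate_corpus(ms.GeneratorConfig(n_reports=500, seed=7))
train, test = ms.chronological_split(corpus, 0.8)   # 400 / 100 reports

assigner = ms.fit_section_assigner(train.blocks, n=1, k=10, seed=1)
truth = [b.true_section for b in test.blocks]
print("one-stage accuracy:", round(ms.model_accuracy(assigner.predict(test.blocks), truth), 3))

two_stage = ms.fit_two_stage(assigner, train, seed=5)
print("two-stage accuracy:", round(ms.model_accuracy(two_stage.predict(test), truth), 3))
print("target cluster:", two_stage.target_cluster)
```

prints

```
one-stage accuracy: 0.97
two-stage accuracy: 0.981
target cluster: 9
```

The one-stage number is the fraction of the 925 held-out test blocks
whose predicted section matches the header they were cut from; the
two-stage model re-classifies only the blocks that land in the least pure
first-stage cluster (here cluster 9) and leaves every other prediction
untouched, which is where the improvement comes from.

The same pipeline is scriptable from the shell:

```
marrowsect generate --n-reports 500 --seed 7 --out reports/
marrowsect split --input reports/ --out splits/
marrowsect train --input splits/train.jsonl --n 1 --k 10 --ensemble --out model.json
marrowsect predict --model model.json --input splits/test.jsonl --out predictions.jsonl
marrowsect evaluate --model model.json --input splits/test.jsonl
marrowsect experiment --seed 7 --out grid/
```

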