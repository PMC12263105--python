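# aopminer

Dictionary-driven text mining of literature abstracts for building
**Adverse Outcome Pathway (AOP) networks**.

An AOP organizes toxicological knowledge as a chain from a molecular
initiating event (MIE), through key events (KEs), to an adverse outcome
(AO), triggered by a stressor such as a chemical or ionizing radiation.
Curating these chains by hand from thousands of abstracts is slow;
`aopminer` automates the evidence-gathering step for toxicologists and
AOP curators.  Given an abstract corpus, a stressor dictionary and a
biological-event dictionary (with synonyms), it:

1. **standardizes** all text identically — lowercase tokenization,
   stopword removal, Porter stemming, synonym expansion;
2. **detects** terms in each abstract under one of two regimes: the
   *partial* rule (at least ¾ of a term's content words present,
   `4j ≥ 3k` in integer arithmetic) or the *exact* rule (all words
   present, fewer false positives);
3. **links** term pairs co-mentioned in the same abstract
   (stressor–event and/or event–event searches) and scores each link
   with a one-sided **Fisher exact test**: for a pair detected in
   abstract sets *A* and *B* within a corpus of *N* abstracts,

   *p* = P(X ≥ |A∩B|),  X ~ Hypergeometric(N, |A|, |B|),

   then bins (count, *p*) into a confidence category
   Low < Moderate < High < Very High;
4. **annotates** detected events from local extracts of AOP-Wiki, KEGG,
   Reactome, WikiPathways, UniProt, HPA, DISEASES and DisGeNET, using
   the same normalization (gene symbols match by identity);
5. **exports** the undirected, weighted, confidence-colored network as
   viewer-ready JSON and Cytoscape-readable TSV tables, with count and
   confidence filters.

A synthetic-corpus generator (`aopminer.synth`) plants known
co-occurrence structure so every stage can be validated against ground
truth without any database or PubMed access.

## Worked example

`examples/01_mine_links.py` builds the built-in planted study corpus
(2 stressors, 10 events, 200 abstracts of which 50 are background) and
mines it:

```text
corpus: 200 abstracts
detected 248 (term, abstract) hits

18 links (top 5 by co-occurrence count):
  radon                     -- oxidative stress          stressor-event  count=15
  radon                     -- dna double strand breaks  stressor-event  count=12
  radon                     -- apoptosis                 stressor-event  count=10
  radon                     -- lung cancer               stressor-event  count=9
  radon                     -- tp53                      stressor-event  count=8

all 18 planted pair counts recovered exactly: True
```

Each `count` is the number of abstracts co-mentioning the pair; because
the corpus is planted, recovery can be checked exactly.
`examples/02_fisher_confidence.py` scores the same links — note that
`radon -- lung cancer` has 9 co-mentions yet *p* = 0.057 (Low): both
terms are individually frequent, so the overlap is not surprising under
independence, which is exactly what the Fisher test guards against.
The other examples demonstrate annotation
(`03_annotate_events.py`, 25 annotations recovered per plan) and
network filtering/export (`04_build_and_export_network.py`).

## Command line

```bash
aopminer run --corpus corpus.tsv --stressors stressors.tsv \
    --events events.tsv --kinds stressor-event,event-event \
    --match partial --scope abstract --annotate extracts/ \
    --min-count 2 --min-confidence Moderate --out results/
aopminer synth --spec spec.json --out fixtures/
```

`run` writes `network.json`, `edges.tsv`, `nodes.tsv`,
`annotations.tsv` and `run_metadata.json`; identical inputs give
byte-identical outputs.  Input formats (corpus TSV or MEDLINE tagged
export, dictionary TSV, annotation TSV) are documented in
`docs/methods.md`.

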