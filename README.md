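# immunopep

Immunogenicity scoring for MHC class I presented peptides.

Not every peptide presented on an MHC class I molecule triggers a CD8⁺
T-cell response: even among well-presented 9mers, roughly half are never
recognized. `immunopep` implements a linear scoring model that captures
which amino acids T-cell receptors prefer to see — large and aromatic
residues such as tryptophan and phenylalanine raise the odds of
recognition, while small residues such as serine lower them — together
with the full statistical toolkit used to build and validate such a model
from labelled epitope data. It is aimed at immunoinformaticians doing
epitope discovery (triaging candidate peptides before expensive T-cell
assays) and at anyone studying the sequence determinants of TCR
recognition.

## The model

A 9mer ligand `L` presented on MHC molecule `H` receives the score

```
S(L, H) = Σ_p  M(H, p) · I(p) · E(A(L, p))
```

where, for each peptide position `p`:

- `E(a)` is the **log-enrichment score** of amino acid `a`: the natural
  log of the ratio of `a`'s frequency at non-anchor positions of
  immunogenic vs non-immunogenic peptides;
- `I(p)` is the **importance weight** of the position: the
  Kullback–Leibler divergence between the immunogenic and
  non-immunogenic amino-acid profiles at `p` (positions P4–P6 dominate,
  consistent with TCR contact geometry);
- `M(H, p) ∈ {0, 1}` **masks the anchor positions** of `H` (P1, P2 and
  P9 for most HLA molecules, but e.g. P2/P5/P9 for HLA-B*08:01), so that
  binding-motif residues never masquerade as T-cell preferences.

A positive score predicts an immunogenic peptide. The package ships the
published reference scale (20 scores, 9 weights, the default mask rule
plus the B*08:01 exception) and can retrain `E` from any labelled 9mer
data set, holding `I` fixed.

Around the core model the package implements the supporting machinery
that such analyses need: non-anchor residue counting, source-protein
background frequencies, background-resampling permutation tests with
Storey/BH q-values, Fisher tests of physicochemical classes (large vs
small, aromatic vs non-aromatic, acidic vs basic, charged vs
non-charged), per-position divergence tests, mapping-based redundancy
reduction of database-derived peptide sets, binding-affinity-matched
control sets, stratified cross-validation with ROC/AUC, triage
summaries, and a synthetic-data generator with planted ground truth.

## Worked example

```sh
$ printf 'sequence\tallele\nSLFNTVATL\tHLA-A*0201\nGILGFVFTL\tHLA-A*0201\nKRWIILGLN\tHLA-B*0801\n' > demo.tsv
$ immunopep score --peptides demo.tsv
sequence	allele	score	positive
SLFNTVATL	HLA-A*02:01	0.16385	True
GILGFVFTL	HLA-A*02:01	0.30483999999999994	True
KRWIILGLN	HLA-B*08:01	0.21750000000000003	True
```

For SLFNTVATL on HLA-A*02:01 the anchors P1/P2/P9 are masked and the six
non-anchor residues contribute `0.10·E(F) + 0.31·E(N) + 0.30·E(T) +
0.29·E(V) + 0.26·E(A) + 0.18·E(T) = 0.16385`: a positive score, i.e.
predicted immunogenic. Note the allele spellings are normalized
(`HLA-A*0201` → `HLA-A*02:01`) and that KRWIILGLN is scored with the
B*08:01-specific mask. The same in Python:

```python
>>> import immunopep as ip
>>> model = ip.load_published_model()
>>> ip.score_peptide(model, "SLFNTVATL", "HLA-A*02:01")
0.16385
```

Training and evaluating on your own labelled data:

```python
imm = ip.read_peptide_table("immunogenic.tsv", required_length=9)
non = ip.read_peptide_table("non_immunogenic.tsv", required_length=9)
masks = ip.bundled_mask_table()
result = ip.cross_validate(imm, non, masks, model.importance, k=3, reps=25, seed=1)
result.auc, result.frac_pos_imm, result.frac_pos_non
```

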