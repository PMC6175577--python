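# Methods

## The specificity model

The unit of classification is the *phosphoacceptor window*: the residues
at offsets −6..+2 around a phosphorylated serine or threonine (offset 0),
padded with `-` where the sequence ends.  Two encodings of BRCT1/BRCT2
specificity operate on windows:

**Strict consensus patterns.**  `BRCT1: [FILMV]-[FILMV]-[FILMV]-x-x-[ST]-P`
and `BRCT2: [FILMV]-x-x-[ST]-P`, parsed from Prosite-style text.  Matching
is positional with the [ST] element anchored at offset 0; padding and the
ambiguity code `X` never match, including wildcard positions.  Because the
BRCT1 pattern's last five elements equal the BRCT2 pattern, every strict
BRCT1 match is a strict BRCT2 match (verified exhaustively in the test
suite over all 20⁷ words).  The analytic match-count of a pattern is the
product of its element set sizes (BRCT2: 5·20·20·2·1 = 4,000 of 20⁵;
BRCT1: 100,000 of 20⁷), also verified against exhaustive enumeration.

**Rule-based classifier.**  The strict patterns over-require the +1
proline (a kinase-consensus feature that makes no direct contact with the
BRCT surface) and under-represent what the structures show about −4/−3.
The classifier instead applies:

* BRCT2-compatible ⇔ residue(−3) ∈ {F,I,L,M,V};
* BRCT1-compatible ⇔ all of
  * residue(−3) ∈ {F,I,L,M,V} ∪ {A} — alanine is admitted on the RAD9
    precedent (Ala at −3 occupies the BRCT1 recess), never at −4;
  * residue(−4) ∈ {F,I,L,M,V}, or ∈ {S,T,G,A} in *long* peptide context
    only (see below);
  * residue(−4) ∉ {R,K,E,D,Q,N} — arginine and glutamate are the
    experimentally observed exclusions; K, D, Q, N are extrapolated by
    charge/size analogy and are marked "extrapolated" in the rule trace;
  * residue(−1) ∉ {L,I,F,M,W,K,R} — generalising the observed abolition
    of binding by Leu or Lys at −1 (a steric/electrostatic clash).

Every admission/exclusion appends a record to the decision trace, and
windows whose −5..−1 core contains padding are flagged "truncated
context" but still classified.

`context_mode` ("short", the default, vs "long") captures the observation
that a small polar −4 (the Treslin-pT969 case, Ser at −4) is disfavoured
in a short synthetic peptide but tolerated in longer context.  The
generalisation to the whole {S,T,G,A} set means a long-context window with
Thr at −4 (the Mdb1-pT113 case) is also classed BRCT1-compatible, although
the corresponding short-peptide measurement shows BRCT2 binding only; the
default short mode reproduces the measured outcome.

Relative affinity between two compatible domains is *not* derivable from
these rules; the classifier reports a `preferred` domain only when the
caller supplies external evidence (e.g. phosphate-pocket charge-reversal
mutant FP results), and only if that domain is in the compatible set.
Phosphotyrosine is rejected throughout: the patterns and windows accept
S/T acceptors only.

## Substitution-tolerance table

The RAD9-tail pull-down panel systematically substituted positions −5,
−4, −3 and −1 around pSer387 (native context V-L-A-…-D).  Categories are
an ordinal encoding TIGHT=2 / REDUCED=1 / ABOLISHED=0; residues the panel
never probed score UNKNOWN (=1, i.e. treated like REDUCED).  Encoded
entries:

| offset | TIGHT | REDUCED | ABOLISHED |
|---|---|---|---|
| −5 | V (native), Q, S, F, A | D | — |
| −4 | L (native) | F, I | S, N, A |
| −3 | A (native), V | S, F, D, G, I | — |
| −1 | D (native), S | — | K, L |

Two cells are interpretation choices where the source data are graded
autoradiograph yields rather than printed categories: the −3
substitutions other than Val are encoded REDUCED (only valine *retained
tight* binding; the others were accommodated at lower yield), and the −4
small/polar substitutions are encoded ABOLISHED (only Phe/Ile were
*tolerated*, and then with reduced binding).  Only the orderings the
experiments establish are load-bearing in the tests.

The subsite total (max 8) is the sum over the four offsets; the ranking
score normalises it to [0, 1] and adds a +0.25 bonus when +1 is proline —
a prioritisation cue (proline-directed kinase consensus), deliberately not
a compatibility requirement.

**Monotonicity caveat.**  "A better-tolerated residue never loses a
domain" holds for BRCT1 but cannot hold for BRCT2: at −3 the native
alanine is TIGHT yet BRCT1-specific, while Phe (REDUCED) is
BRCT2-compatible.  This is not an inconsistency — the pull-down probed a
BRCT0,1,2 construct whose RAD9 binding is BRCT1-mediated, so the table is
a BRCT1 tolerance statement.  The property test asserts the BRCT1 form.

## Scanning and triage

Scanning enumerates every S/T position of a protein (1-based,
phosphoacceptor-anchored coordinates), extracts the window, and keeps
positions that match ≥1 strict pattern (`strict` mode) or have non-empty
classifier compatibility (`scored` mode).  Match tables serialise as TSV;
writing is byte-stable and a written table reads back to an equivalent
match list (the rule trace is recomputed from the window).

Candidates are ranked by

```
rank_score = w_motif·motif_score + w_dis·disorder + w_cons·conservation
             + w_phos·[annotated]
```

with default weights (0.4, 0.2, 0.2, 0.2) — an arbitrary but exposed
choice; only ordinal behaviour (monotonicity in each coordinate,
permutation invariance, stable (id, position) tie-break) is guaranteed or
tested.  Weights must sum to 1.

* *Disorder* is the TOP-IDP per-residue propensity scale, min-max rescaled
  to [0, 1] (Trp → 0, Pro → 1), averaged over a ±10-residue window.  This
  is a deliberately lightweight heuristic standing in for a disorder
  predictor; callers can supply precomputed per-residue scores instead.
* *Conservation* is the fraction of orthologue windows (aligned on the
  phosphoacceptor, caller-supplied) whose compatibility set is a superset
  of the query's — motif-class preservation, not residue identity.  An
  empty orthologue list yields a missing value, which ranking maps to an
  uninformative 0.5, not to 1.0.

## FP titrations

Simulation draws replicate readings as model value + i.i.d. Gaussian noise
(homoscedastic in mP).  Defaults mirror the assay design: 12-point
two-fold dilution from 50 µM, 4 replicates, 200 nM fluorescein-labelled
probe.  Baseline 80 mP and plateau 220 mP are fixed once as realistic
free/bound polarisation values for such a probe.

Fitting is non-linear least squares (scipy `curve_fit`) of the one-site
specific-binding hyperbola on the replicate-mean curve (replicates enter
figures as mean ± SD; a per-replicate fit is available behind a flag).
Initialisation: baseline = min reading, plateau = max reading, Kd = the
concentration nearest the half-maximal mean; parameter standard errors
come from the fit covariance.  The probe is treated as non-depleting even
though 0.2 µM probe is comparable to sub-µM Kd values — fidelity to the
stated analysis model first; a quadratic probe-depletion model is provided
behind `model="quadratic"` for sensitivity analysis.

**ND rule.**  A titration is *not determined* when any of:

1. the optimiser fails to converge;
2. fitted Kd > 1.0 × the highest tested concentration (extrapolated);
3. fitted Kd < 1.0 × the lowest tested concentration — the curve would be
   saturated before the first point, so the baseline is an extrapolation
   and the Kd unidentifiable.  Without this symmetric lower bound, ~15% of
   pure-noise titrations escape as degenerate near-zero-Kd fits with
   absurd baselines (≈ −10⁴ mP);
4. fitted dynamic range (plateau − baseline) < 3 × the residual SD of the
   mean curve, or ≤ 0 (non-binding response shape).

Thresholds (3 SDs; factors 1.0 on both concentration bounds) are this
package's operationalisation of an otherwise qualitative ND call.  Under
these rules pure-noise titrations are called ND in ≥95% of seeds while
RAD9-like (2.1 µM) and 10-fold-tighter RHNO1-like (0.21 µM) curves are
always determinable.

`kd_ratio(fit_a, fit_b)` returns Kd(b)/Kd(a) — *a* is the tighter binder
by convention — and refuses ND inputs.

## Synthetic data

The generators define the conditions the tests and acceptance runs use:

* **Proteomes**: i.i.d. background residues (uniform by default, so the
  analytic false-positive rate `count/20^L` per eligible position is
  exact; an approximate human composition is available), with consensus
  windows planted at known positions ≥6 residues from sequence ends and
  ≥9 apart.  Planted windows sample *every* element uniformly from its
  allowed set — wildcards included — so planted sites also exercise
  classifier edge cases (e.g. a planted −1 Lys gives a strict-matching
  but BRCT1-excluded site).  Truth tables are exhaustive.
* **Orthologue sets**: each orthologue preserves the query's
  compatibility with the given probability; non-preserving orthologues
  receive a disqualifying −3→Asp (or, for BRCT1-compatible queries,
  sometimes −4→Arg) substitution.  A query with empty compatibility
  cannot be degraded further and is returned unchanged.
* **Fixture panel**: the seven fluorescent assay peptides, the three
  crystallisation peptides, a synthetic −4-arginine window standing in
  for the Crb2-pT235 class (its flanking sequence is not part of the
  packaged data, so the window is constructed, and labelled synthetic),
  and the 21-row RAD9 substitution pull-down panel — each with expected
  outcomes regression-locked against the classifier.

What the synthetic data do *not* emulate: real proteome length and
composition structure beyond the composition flag, correlated
(heteroscedastic or concentration-dependent) FP noise, probe depletion
(unless simulated with the quadratic model), and orthologue divergence
outside the −4/−3 disqualification channel.  Passing benchmarks therefore
demonstrate correctness of the pipeline under its stated model, not
performance on real proteomes or plates.

## Problem sizes and numerics

The packaged benchmarks use 100-seed Monte-Carlo runs for Kd recovery
(median within ±20%) and ratio recovery (±25%), a 150-protein × ~500-residue
background proteome for false-positive calibration, and full exhaustive
enumeration of all 20⁵ and 20⁷ words for the pattern-count oracle (chunked
numpy passes, most selective position first).  Noiseless fits recover
generating parameters to better than 1e-6 relative; fitted Kd is invariant
under joint rescaling of concentration units.  Ties in ranking are broken
deterministically; all generators take explicit seeds.

## Known limitations

* The classifier is a sequence model of a structural phenomenon; it does
  not predict affinity, and compatibility is necessary but not sufficient
  for in-vivo partnership (BLM/FANCJ windows pass BRCT2 rules yet bind
  other TOPBP1 modules).
* BRCT2 behaviour at −1 is unscored (untested experimentally); the −1
  exclusion applies to BRCT1 only.
* The −5 Asp penalty affects ranking only, never compatibility.
* BRCT4,5 and BRCT7,8 specificities are out of scope.
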