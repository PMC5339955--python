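# Methods

## The observation model

A culture-based endophyte survey samples tissues (leaf, root, flower),
plates surface-sterilized fragments, and records one row per isolate
that grows out: an isolate code carrying a tissue suffix (L/R/F), a
species-level label from ITS sequencing, and accession metadata. The
package treats this table as a multinomial sample per tissue from that
tissue's underlying endophyte community — the same assumption the
synthetic generator uses — and all community statistics are computed
from the resulting taxon × tissue count matrix.

### Taxon identity

Species labels are normalized (whitespace collapsed, trailing period
stripped unless part of an "sp."/"spp." epithet, case-insensitive
comparison) and then resolved in one of two modes:

- `label` (default): equal labels are one taxon across tissues. This
  is the convention behind the pairwise similarity tables, where e.g. a
  leaf–root pair sharing exactly "Cladosporium sp." gives a = 1.
- `label_per_tissue`: a taxon is a (label, tissue) pair. This is the
  conservative reading for indeterminate labels — "Cladosporium sp."
  cultured from roots cannot be proven conspecific with "Cladosporium
  sp." from leaves — and changes pooled richness, hence every
  multi-sample beta value.

Both modes are first-class because real surveys mix the two readings:
the packaged survey's own published similarity values imply merged
labels while its global Whittaker figure implies a pooled richness
between the two modes (see Limitations). Genus statistics always use
the label's first token; anamorph/teleomorph pairs (Fusarium vs
Gibberella, Aspergillus vs Neosartorya) are deliberately not folded.

## Alpha diversity

All formulas are the classical ones over positive counts, natural
logarithms throughout (the packaged survey's Shannon values equal the
ln-based computation exactly). Two deliberate estimator choices:

- Simpson's dominance is the plug-in Σpᵢ² rather than the unbiased
  Σnᵢ(nᵢ−1)/(N(N−1)); only the plug-in form gives D = 0.5 for a
  two-singleton assemblage, matching PAST and the survey tables.
- Chao-1 is the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), which is
  defined even with no doubletons (F₂ = 0), the relevant case for
  sparse culture collections.

Brillouin uses log-gamma, so factorials never overflow. Fisher's α
solves S = α ln(1 + N/α) by bracketed Brent root-finding (residual
< 1e−9; a property test checks agreement with a 200-step bisection
oracle and monotonicity in S). The left side is increasing in α with
supremum N, so the root exists and is unique iff S < N; at S = N the
index diverges and is carried as "undefined" (NaN in full-precision
output, 0 in table-compat mode — the convention desktop packages print).

### Table-compat rendering

Published versions of these tables are transcribed from a desktop
display that shows 4 significant digits; transcription then drops
digits beyond the third decimal without rounding. The compat renderer
(`alpha.round_table_compat`) therefore rounds to 4 significant digits
and truncates at the third decimal: 0.21875 → 0.218, ln2/2 = 0.34657 →
0.346, 1/ln2 = 1.4427 → 1.443, 10.9051 → 10.91. A plain half-up
3-decimal rounding reproduces most but not all such cells; the two-step
convention reproduces the packaged survey's 39-cell table exactly.
Full-precision values are always available; rendering never feeds back
into computation.

## Beta diversity

Pairwise similarity uses the presence-overlap decomposition (a shared,
b and c unique) with Sorensen QS = 2a/(2a+b+c) and Jaccard
JS = a/(a+b+c); JS = QS/(2−QS) holds algebraically and is property-
tested. The rendered grid follows the field's compact layout: Sorensen
above the diagonal, Jaccard below.

The multi-sample suite follows the Koleff/Wilson–Shmida compendium
definitions (also PAST's): Whittaker βw = S/ᾱ − 1; Cody (g+l)/2;
Wilson–Shmida (g+l)/(2ᾱ); Mourelle βt/(n−1); Harrison β1 = βw/(n−1)
and β2 = (S/α_max − 1)/(n−1); Williams 1 − α_max/S; Routledge
S²/(2r+S) − 1 with r the number of unordered species pairs co-occurring
in ≥ 1 sample (checked against a brute-force double loop). Gradient-
dependent indices use the declared sample order, defaulting to the
matrix column order (leaf, root, flower); Whittaker and Routledge are
order-free, which is property-tested by permutation.

## Bioactivity screens

**%GI.** Percent growth inhibition is blank-subtracted:
(1 − (ODₜ − OD_b)/(OD_c − OD_b))·100. This is the standard MTT
computation; it is affine-invariant in the three absorbances (property-
tested), so plate scaling and offsets cancel. Screening counts use a
strict ">" at the 50 % threshold.

**IC50.** Censoring is decided before fitting: ≥ 50 % inhibition at the
lowest tested concentration (10 µg/mL in the packaged panels) reports
"< min"; < 50 % at the highest reports "> max". Otherwise a 4PL
%GI(c) = lower + (upper−lower)/(1 + (IC50/c)^hill) is fitted by
bounded least squares on log-concentration, and the reported value is
the fitted curve's 50 % crossing (identical to the IC50 parameter when
lower = 0, upper = 100). If the fit fails or degenerates, the estimate
falls back to log-linear interpolation between the two points
bracketing 50 %. With four tested concentrations the noise-free fit is
exact (round-trip recovery to 1e−6 is tested); at 2 % additive noise
the median absolute relative error over 200 simulated curves is below
5 %, and censoring decisions agree with noise-free truth in > 95 % of
curves. Potency counts treat a "<10" entry as active at any threshold
above 10 and never count "> max" entries.

**Disc diffusion.** Activity is the presence of a recorded zone;
"mean ± sd" cells are parsed but only the mean participates. Fractions
are over the full extract panel, inactive rows included.

**MIC.** The endpoint is the lowest concentration with no growth such
that no growth occurs at any higher tested concentration. Growth at
every concentration right-censors ("> max"); clearance at every
concentration reports the lowest with a left-censor note (the value a
report prints as a plain "12.5"). Growth reappearing above a clear
concentration is flagged as an invalid well rather than silently
resolved. Screen counts require at least one non-right-censored
MIC ≤ cutoff (100 µg/mL by default, the top of the tested series).

## Synthetic data

The generator mirrors the three observation processes with defaults
matching the assays it emulates: communities are per-tissue multinomial
draws (the packaged survey's empirical compositions are available as a
spec); MTT plates are built by inverting the %GI formula around fixed
blank/control anchors so that blank-subtraction recovers 4PL(c) plus
Gaussian noise on the %GI scale (noise on %GI rather than OD keeps the
truth expressible in the fitted model's units); dilution series grow
exactly below a latent true MIC from the 12.5–100 µg/mL series, with an
optional per-well misclassification rate. Tested concentration grids
default to 10/25/50/100 µg/mL (MTT) and 12.5/25/50/100 µg/mL
(dilution). All generators are pure functions of (spec, seed).

What the simulations do not emulate: culture bias (taxa that never
grow on the medium), plate-position and edge effects, correlated
replicate noise, and dose-response curves whose plateaus drift between
plates. Passing recovery tests therefore show estimator correctness
under the stated sampling model, not robustness to those real-world
artifacts.

Study sizes used in tests and the acceptance script — 200 dose-response
curves at σ = 2 %, 5 000 isolates over 50 even taxa, 250 dilution
series — are the package's chosen desk-scale study conditions; they
complete in seconds while leaving binomial/fit error well inside the
asserted bounds.

## Known limitations

- The packaged survey's published global beta list is internally
  inconsistent: its Whittaker value (1.7692) implies pooled richness
  24 over mean tissue richness 26/3, but merging shared labels gives
  S = 23 (βw = 1.6538) and keeping tissues distinct gives S = 26
  (βw = 2.0). No taxon-resolution rule of the isolate table yields 24,
  so the package reports the two defensible values rather than the
  printed one; the remaining printed suite values are likewise not
  reproducible under any single definition set and are provided per
  the stated definitions only.
- Genus-level class composition depends entirely on the shipped
  taxonomy map (an editable TSV); alternative genus→class readings
  produce different percentages, which is why the map is data, not
  code.
- IC50 values are point estimates; no confidence intervals are
  propagated from the fit.
- MBC annotations are carried as flags; no bactericidal/bacteriostatic
  arithmetic is attempted.
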