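# Methods

This note documents the models implemented in `channeliphys`, the
conventions and defaults chosen where the underlying methods literature is
silent, and what the synthetic-data generators do and do not emulate.

## Electrodiffusion and reversal potentials

Bi-ionic I-V families are generated from the Goldman-Hodgkin-Katz (GHK)
constant-field current equation, summed over ions. For an ion of valence z
with internal/external concentrations C_in, C_out and relative
permeability P:

    I_z(V) ∝ P z² u · (C_in − C_out e^(−zu)) / (1 − e^(−zu)),  u = FV/RT

with a series expansion used near u = 0. Divalents use the z = 2 form,
consistent with the 4·[Ca] factor of the divalent bi-ionic permeability
equation (both follow from the same constant-field assumptions). The
overall current scale is an arbitrary gain (relative permeabilities carry
no absolute units), default 100 pA per unit flux, chosen to give currents
of realistic magnitude (hundreds of pA at ±100 mV for 150 mM solutions).
The generator models peak-current summaries only: no channel gating
kinetics, no series-resistance or liquid-junction corrections, no
capacitance transients.

The reversal-potential estimator fits a degree-9 polynomial to the I-V
series. Two numerical choices matter:

* **Conditioning.** A degree-9 fit on voltages in raw mV is severely
  ill-conditioned; voltages are mapped to [−1, 1]
  (`numpy.polynomial.Polynomial.fit`) and roots mapped back. This changes
  nothing about the method, only its numerics.
* **Root selection.** A degree-9 polynomial has up to nine real roots; the
  estimator takes the real root bracketed by the empirical sign change of
  the measured current, breaking ties by proximity to the
  linear-interpolation zero crossing. Series whose current never changes
  sign (strongly rectifying channels) raise a "no reversal in range" error
  rather than extrapolating.
* With fewer than degree + 2 points the degree is reduced to n − 2 and the
  reduction is recorded in the diagnostics.

Validation: across random GHK conditions the estimator agrees with a
bisection root-finder applied to the same GHK current sum to better than
0.1 mV (typically 0.02 mV), and symmetric-Na series reverse within
0.5 mV of 0.

## Conductance and normalization

G = I/(V − V_rev) diverges at V_rev; voltages within a guard band
(default half-width 2.5 mV, roughly a quarter of the standard 10 mV
voltage step) are flagged as excluded but retained in the container, so
no data is silently dropped. Two normalizations are supported — to the
maximum conductance and to the value at an anchor voltage (e.g. −100 mV
for I-V families) — and the mode plus reference value are recorded in the
series, because comparisons such as the conductance difference at 0 mV
are meaningless across modes and the code refuses to mix them.

## Bi-ionic permeability

Monovalent/monovalent: P_X/P_Na = exp(F ΔE_rev/RT). Monovalent-in /
divalent-out uses the Lewis bi-ionic form

    pCa/pX = ([X]_in / (4[Ca]_out)) · e^u · (1 + e^u),  u = E_rev F/RT.

A variant with trailing factor (e^u − 1) circulates in print; it yields
negative ratios for any negative reversal potential and cannot be a
permeability. The Lewis form is the default; the other is available
behind `as_printed=True` for auditability and raises when the result is
non-positive. Concentrations are used as activities (no activity
coefficients), and constants default to F = 96485.33 C/mol,
R = 8.314463 J/(K·mol), T = 294 K.

## The single permeant blocker model

Equilibrium block of an open channel by an internal cationic blocker that
can itself permeate:

    G(V) = G_max / (1 + [Spm]/K_d(V)),   K_d(V) = g e^(V/h) + L e^(V/k)

* g = k_off/k_on and L = k_perm/k_on at 0 mV. The three rate constants are
  not separately identifiable from equilibrium G-V data; only the ratios
  are estimated, and K_d(0 mV) = g + L by construction.
* Sign convention: h < 0 (occupancy grows with depolarization), k > 0
  (relief by permeation at strong depolarization). These are enforced as
  bound constraints.
* [Spm] is a fixed input, never a free parameter: doubling [Spm] and
  doubling (g, L) leaves G(V) identical, so a free [Spm] is perfectly
  confounded. This invariance is asserted as a test.

Fitting choices (the source methods state none): optimization runs in
log-space for g and L (positivity without active bounds), raw space for
h and k with sign bounds, unweighted least squares by default with
optional per-point weights. Initialization takes K_d(0) from the
conductance nearest 0 mV via K_d = [Spm]·G/(G_max − G) with G_max
initialized at the observed maximum, split 85:15 between g and L
(only the sum is constrained near 0 mV; the split is resolved by the
voltage wings, and the g-L estimate correlation is reported as a
diagnostic), h₀ = −20 mV, k₀ = +30 mV. On normalized data G_max is
fitted within [0.8, 1.2] by default; it can be pinned with `fix_gmax`.
A voltage window restricts the objective to the requested range (used
when large-conductance states contaminate one end of the G-V).

Refusal rather than garbage: when the G-V dip is shallower than 2% of the
maximum, the data carry no information about the blocker and the result
is flagged non-converged with a "no detectable block" message; [Spm] = 0
is rejected outright.

Block-free (e.g. +4-site alanine) channels are fitted with the intrinsic
exponential G = 1 + (G_0 − 1)e^(V/V_c). For a two-parameter model a
reported (G_0, G_min, V_c) triple is redundant; the implementation
reports the fitted parameters plus the empirically observed minimum
conductance separately. Constant conductance leaves V_c unidentifiable
and is flagged.

Validation: noise-free self-generated data are recovered to ≤ 0.1%
relative error; at 5% additive noise on the −100…+100 mV Δ10 grid the
median K_d(0) error over 50 seeds is ~8%.

## Dose-response and recovery kinetics

Hill activation y = 1/(1 + (EC50/c)^p) and monophasic inhibition
y = 1/(1 + (c/IC50)^p) are fitted on the log10-concentration axis;
midpoints are reported in the units of the input table (a unit tag rides
along). Zero-concentration control rows are valid anchors (y = 1) for the
inhibition-direction models and are dropped for activation fits.
Responses are not constrained to ≤ 1: normalization is to the
ligand-alone response, and potentiating compounds legitimately exceed 1.

The biphasic model is a product of one stimulatory and one inhibitory
Hill term,

    y(c) = (1 + a·c^ps/(EC50_s^ps + c^ps)) · (1 − c^pi/(IC50_i^pi + c^pi)),

chosen as the simplest form with exactly one stimulatory and one
inhibitory phase; published biphasic-fit software may parameterize
differently, so only the midpoints should be compared across tools.
Setting the stimulatory amplitude to zero reduces it exactly to the
inhibition model (asserted as a nested-model test). When the fitted
amplitude collapses to ~0 the result notes the single-phase fallback.

Recovery from desensitization uses the decaying exponential
y(x) = 1 + A·e^(−x/τ) with A ≤ 0, so the paired-pulse ratio rises from
1 + A toward 1. (The growing-exponent form sometimes printed, e^(x/τ),
diverges and cannot describe a recovery curve; the sign is treated as a
typo.) Fully-recovered data (A ≈ 0) leave τ unidentifiable and are
flagged.

## Ligand-specificity annotation

Queries are globally aligned to a mature-GluA2-numbered reference
(Biopython `PairwiseAligner`, BLOSUM62, gap open −11 / extend −1, free
end gaps), and a strictly monotone position map is read off the aligned
blocks. The alignment parameters are package defaults — the numbering
convention itself does not prescribe them. Coverage is judged over the
440–740 span containing every annotated site; below 30% the mapping is
rejected as unreliable. For distant homologs the two ligand-binding-domain
segments (S1/S2) can be aligned as separate fragments, which the free
end-gap scoring supports.

Annotated positions (mature GluA2 numbering): backbone-contact sites
450, 478, 480, 485, 654, 705; side-chain-contact sites 653, 655, 704,
708, 732; the Q/R/N pore-apex site 607 and the +4 site 611 (anchored by
the standard mutant names Q607S and D611A); the SYTANLAAF gate motif with
its lurcher alanine; and the site-G alanine-threonine pair. The +4
residue is read four residues downstream of the Q/R/N residue in the
query's own ungapped coordinates, not four alignment columns. Sites
deleted inside the aligned span report a gap; sites outside it report
"unmapped"; both warn and both make the specificity call "unpredictable"
if they hit a rule position.

The specificity rules: glutamate iff 653 ∈ {G,S,T} ∧ 655 = T ∧ 732 = Y;
glycine/D-serine iff 653 = S ∧ 655 ∈ {V,L,A,I,P} ∧ 732 = F; otherwise
unpredictable. The two rule sets are disjoint (655/732 requirements
conflict), verified by exhaustive sweep over all 20³ triples. Missing
backbone contacts (no D at 705, no R at 485) produce warnings —
receptors lacking them are known to behave atypically — but never change
the label. Position 654 is extracted but participates in no rule.
SYTANLAAF/lurcher/site-G extraction is annotation only.

**The bundled reference is synthetic.** It is a deterministic
pseudo-random 850-mer carrying the canonical GluA2 residues at every
annotated position, sufficient for coordinate-driven annotation and for
fixture generation; it is not the biological P19491 sequence, and
alignments of real receptor sequences against it will be dominated by the
planted anchor regions. Users with the real mature GluA2 sequence should
pass it as `reference_seq` (with `signal_peptide_offset` for full-length
precursors); all positional logic is unchanged.

## Synthetic data: what it does and does not emulate

Generators draw additive Gaussian noise with standard deviation expressed
as a fraction of the maximum absolute noise-free signal — the simplest
model sufficient for parameter-recovery testing. Real recordings have
structured noise (series-resistance errors, rundown, seal drift,
cell-to-cell parameter variation), none of which is modelled; passing
recovery tests therefore demonstrates correctness of the fitting code
under the stated noise model, not robustness to every experimental
artifact. Default study conditions: command voltages −100…+100 mV in
10 mV steps, 30 µM internal spermine, T = 294 K, blocker truth
K_d(0) = 11.4 µM (split 10 : 1.4 between g and L — the split within the
sum is a package choice), h = −18.5 mV, k = 36.5 mV; dose-response truth
EC50 = 0.11 mM; recovery truth τ = 184 ms with amplitude −0.9. Recovery
test tolerances (10% median EC50/K_d error, 15% median τ error at 5%
noise) were calibrated by repeated-seed simulation under these
conditions.

## Problem sizes

The validation suite and the reproduction script run at desk scale: 21-
or 101-point voltage grids, 8–12 concentration points, 10 recovery
intervals, 50 seeds per stochastic recovery suite, 100 random conditions
for the reversal-oracle comparison. These sizes were chosen to match the
scale of the corresponding experiments (5–10 patches per condition,
8-point dose series) while keeping every suite comfortably fast.

## Known limitations

* No kinetic (rate-level) modelling anywhere: gating, desensitization
  onset, and blocker kinetics are out of scope; only equilibrium and
  peak-summary quantities are treated.
* The GHK generator assumes independence of ion movement
  (constant-field); channels with multi-ion pores deviate.
* The biphasic parameterization is one of several in use; amplitudes and
  slopes are not comparable across software, only midpoints.
* The classifier is a residue rule, not a binding model: it reproduces
  the documented specificity classes but cannot score affinity, and
  profiles outside both rules are deliberately left "unpredictable"
  rather than guessed.
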