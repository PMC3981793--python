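# Methods

## The scan

The tool answers one question: *where along an RNA sequence does predicted
secondary structure respond to a temperature change?* Every window of size
w ∈ [wmin, wmax], advanced 1 nt at a time, is folded independently at the
reference temperature T₁ and the shock temperature T₂. The base-pair
distance between the two predictions (|symmetric difference of pair sets|)
becomes a dot at (window start, window end). Intensities are normalized by
the scan's global maximum distance — the plot is relative by construction,
and a scan with no structural change anywhere is entirely blank. The
normalization is global across window sizes rather than per size: the plot
is meant to be read as one picture, and per-size normalization would let a
weakly responding size class masquerade as a strong signal.

Windows are 1-based and inclusive on both ends; the step is fixed at 1 nt.
A window range below 50 or above 150 nt triggers a warning (not an error):
outside that envelope, single-window energy-minimization predictions are
increasingly unreliable. Equal temperatures are allowed (the scan is then
identically zero) but warned about. Dots from different window sizes cannot
collide at the same (x, y), since y − x + 1 determines the size.

The per-position profile reported alongside the dots is the mean intensity
of all windows covering each nucleotide. It is a reading aid for the dot
plot, not a significance statistic: no null model is attached to it, and
deciding whether a cluster is "real" remains a qualitative judgement (or a
job for a future statistical layer).

## The built-in folding model

The engine implements a deliberately reduced nearest-neighbor model chosen
so that every prediction is exactly checkable against brute-force
enumeration:

* **Stacks.** Each adjacent pair of base pairs contributes
  ΔG(T) = ΔH − T·ΔS, with ΔH, ΔS read from a 36-context table
  (ordered outer/inner pair over the six canonical pairs AU, UA, CG, GC,
  GU, UG, symmetric under strand reversal). Negative ΔH and ΔS make every
  stack stabilizing at low temperature and weaker as T rises — the physical
  origin of hairpin melting in the model.
* **Loops.** Hairpin (size ≥ 3) and internal/bulge loops (total unpaired
  1–30, capped in the DP) are tabulated as ΔG at 37 °C and rescaled purely
  entropically, ΔG(T) = (T/310.15 K)·ΔG37; sizes beyond the tables use the
  Jacobson–Stockmayer form ΔG37(s) = ΔG37(s_max) + 1.75·R·310.15·ln(s/s_max),
  R = 1.98717×10⁻³ kcal/(mol·K).
* **Everything else is zero.** No multibranch penalties, dangling ends,
  terminal-AU penalties, special tetraloops, or coaxial stacking. Lonely
  pairs are permitted. Minimum hairpin loop is 3 nt.

The shipped table (`data/nn_params_v1.tsv`, version `builtin-reduced-v1`)
is a human-readable stand-in loosely modeled on published nearest-neighbor
magnitudes (strong CG stacks near −3 kcal/mol at 37 °C, weak wobble stacks
near −0.6). Two deliberate properties matter more than any individual
number: the ΔH/ΔG37 ratios (5.5–7.5) give steep, cooperative melting, and
the weak end of the stack spectrum is weak enough that 8–12 bp stems can
have melting temperatures in the physiological 30–50 °C range. All tests
read the same file, so correctness never depends on specific values. Users
who need real thermodynamics should use the ViennaRNA adapter; the builtin
engine's purpose is a transparent, self-contained, provably consistent
model.

## Algorithms

*MFE.* A Zuker-style dynamic program over interval tables: V(i,j) (best
energy with i·j paired: hairpin, stack/internal loop up to the 30-nt cap, or
multibranch), M/M2 (best arrangements with ≥1 / ≥2 branches) and F (best
structure on the interval). Because multibranch and exterior terms are zero,
the DP's model is identical to the explicit structure-scoring function used
by the enumeration oracle, and equality is exact, not approximate. Traceback
ties are broken deterministically (hairpin, then stacking, then smallest
interior loop, then smallest split point), so repeated runs return identical
structures.

*Partition function.* McCaskill-style inside recursions (Z, Zb, Zm, Zm2)
mirror the MFE decomposition; rightmost-branch splitting makes the counting
unambiguous, so Z is exactly the Boltzmann sum over the enumerable ensemble.
Pair probabilities come from an outside pass (external, internal-loop, and
multibranch-sibling contexts). The centroid is the set of pairs with
p > 0.5, which in a pseudoknot-free ensemble is always a valid structure.

*Banding.* All tables are interval tables — cell (i, j) depends only on the
subsequence i..j — so a scan computes one banded table set per temperature
(band = largest window) and reads every window's MFE structure out by
traceback, instead of folding ~10³–10⁴ windows separately. This is an
optimization with no contract effect; a test verifies banded scan results
against independent per-window folds. Centroid-mode scans share the inside
tables but run one outside pass per window, so they are noticeably slower
than MFE scans.

Numerical notes: energies are exact floats (no rounding during DP);
Boltzmann factors stay far from double overflow for window sizes up to a
few hundred nt at biological temperatures; probabilities from the outside
pass are validated against enumeration to 10⁻⁹ relative error in the test
suite.

## Synthetic thermometer generator

The generator produces the positive and negative controls that make
detection testable: a sequence known to contain exactly one
temperature-switching hairpin at a known location, and a control with none.

*Hairpin design.* The melting temperature of a designed stem-loop is
defined in closed form from the model: Tm is the root of
ΔG(T) = ΣΔH_stack − T·(ΣΔS_stack − ΔG37_hairpin/310.15). A seeded local
search over stem pair compositions moves single positions toward the target
bracket (strengthening or weakening), with orientation flips as fine moves,
and accepts a composition only after the builtin engine confirms the
hairpin folds to exactly the designed structure at and 5 °C below tm_low
and to the open chain at and 5 °C above tm_high. Infeasible brackets fail
loudly with the achievable Tm range. Under the shipped table, 8–11 bp stems
reach Tm ∈ (37, 42) °C with a 4-nt loop; a 12-bp stem needs a 5-nt loop
(the extra loop entropy offsets the additional stacks) — the generator
reports exactly this when asked for the infeasible combination.

*Context.* A hairpin whose ΔG at the reference temperature is necessarily
marginal (that is what a physiological Tm means) is easily destroyed by
stronger chimeric helices between stem bases and flank bases. Flanks are
therefore sampled A-dominant (weights A 0.92, C 0.02, G 0.02, U 0.04):
adenosine pairs only with U, and the designer additionally forbids adjacent
U's on either stem side, so flank–stem contacts are limited to unstackable
lone pairs, which are never stable in the model. Flanks are
rejection-sampled until their standalone MFE at tm_low is ≥ −0.5 kcal/mol
(up to 1000 attempts), and the assembled record is verified to keep the
designed stem in its cold MFE and lose it in its hot MFE. Everything is
reproducible from the ThermometerSpec seed.

*What this does and does not show.* Passing detection on generator output
shows the pipeline is sound: a real structural switch inside quiet flanks
is found and localized. It does not show field performance on natural
5′ UTRs, whose flanks are structured, whose thermometers melt gradually and
partially, and whose thermodynamics need the full Turner model (known
thermometer families — FourU, ROSE — are reported not to show clean
predicted-structure switches at all). The generator is a correctness
instrument, not a realism claim.

## Defaults and parameters

| Parameter | Default | Why |
|---|---|---|
| t1 / t2 | 37 / 40 °C | body temperature vs mild heat shock |
| wmin–wmax | 55–80 nt | window envelope where local predictions are reliable; 50–80 is the recommended working range |
| mode | mfe | centroid available for ensemble-representative structures |
| min hairpin loop | 3 nt | structural minimum |
| internal-loop cap | 30 unpaired | standard DP cap; larger loops are not formed |
| ThermometerSpec | stem 10 bp, loop 4 nt, Tm ∈ (37, 42) °C, flanks 88 nt (200 nt total) | one clean mild-heat-shock switch in an unstructured 5′-UTR-sized context |

Problem sizes used by the test suite and acceptance script — 200 random
sequences of 8–14 nt for the MFE oracle, 50 of ≤ 12 nt for the partition-
function oracle, 1000 random structure triples for the metric laws, one
281-nt scan at windows 55–80, and 20 thermometer + 20 control records of
200 nt scanned at windows 30–50 — were chosen so the full enumeration
oracles stay exact and the whole suite runs in well under a minute on one
core.

## Known limitations

* The reduced model is not quantitative thermodynamics; its structures and
  melting temperatures are internally consistent, not experimentally
  calibrated.
* No pseudoknots, no suboptimal-structure enumeration, no constraint
  folding.
* No statistical significance for dot clusters; interpretation of the plot
  is qualitative by design.
* Ambiguity codes are rejected rather than treated as unpairable: a window
  containing an N would silently change meaning, and failing loudly is
  preferred.
* Long-range interactions spanning more than the largest window are
  invisible to any windowed scan.
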