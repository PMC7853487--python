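# Methods

## Model

The repeated *n*-person public-goods (PG) game, undiscounted, with
implementation error.  Actions are binary (c/d); in the PG parameterization a
round pays ρ·*n*<sub>c</sub>/*n* to each cooperator and 1 + ρ·*n*<sub>c</sub>/*n*
to each defector (1 < ρ < *n*); the donation parameterization pays each
cooperating player *b*/(*n*−1) to every co-player at unit cost (*b* > 1) and
corresponds to ρ = *nb*/(*b* + *n* − 1).  Implementation error flips each
player's executed action independently with probability ε per round.
Long-term payoffs are time averages; for ε > 0 they are expectations under
the unique stationary distribution of the joint-history chain.

Criteria certification uses the PG scheme (payoff *differences* between
players reduce to differences in defection counts, which is what the graph
test needs); evolutionary experiments use the donation scheme with benefit
*b*, matching the conventions of the literature this package follows.

## History encoding

A history profile (the *n* × *m* grid of the last *m* actions) is one
integer: player *i* occupies bits [*im*, (*i*+1)*m*), bit 0 of each field is
the newest round, a set bit is a defection.  Appending a round is a per-field
shift-and-mask; the focal player is row 0; player *i*'s view of a shared
window re-orders rows as (*i*, then the rest in ascending index).  All
statistics the CAPRI rules need (*t*\*, per-player defection counts since
*t*\*, the window-wide defection gap *N*<sub>d</sub>) are popcounts and
trailing-bit scans, vectorized over the whole history space with numpy.

The recovery rule is implemented in its strict form: *every* column except
the newest must be all-defect and the newest must contain exactly *n* − 1
cooperators (the lone defector may be anyone, including the focal player —
otherwise the ε<sup>n−1</sup> escape from mutual defection could not
complete).  A looser reading — requiring only the newest column — is
available behind `strict_recovery=False`; the certifier returns a concrete
positive-gain witness cycle against it (a co-player can milk the repeated
recovery attempts), which is the package's regression guard for this design
point.

## Stationary analysis

`transition_matrix` builds the 2<sup>nm*</sup>-state row-stochastic chain:
from each state, each of the 2<sup>n</sup> realized joint actions receives
probability ∏<sub>i</sub> (ε or 1−ε), with intents marginalized for
stochastic memory-one members.  Solver selection:

* ≤ 2048 states — dense LU on (Mᵀ − I) with one equation replaced by the
  normalization (also the sparse variant, used as an independent
  cross-check).
* larger deterministic profiles — **iterative aggregation/disaggregation
  (IAD)**.  The joint chain is a de Bruijn-type shift graph; sparse LU
  suffers fill-in beyond 10⁸ nonzeros at 2¹⁵ states, and at ε ≤ 10⁻⁴ the
  chain is *metastable*: nearly all mass sits in a cooperative and a
  defective phase exchanging at rates O(ε<sup>n</sup>) and
  O(ε<sup>n−1</sup>), so the spectral gap is O(ε<sup>n−1</sup>) and plain
  power iteration cannot converge.  IAD alternates a few power-iteration
  smoothing sweeps with an exact stationary solve of the chain aggregated
  over the basins of the error-free dynamics (computed by pointer-doubling
  on the deterministic flow).  The aggregation step restores the inter-basin
  mass balance in one shot; the fixed point is the exact stationary vector
  and the iteration stops only when the residual ‖vM − v‖<sub>∞</sub> drops
  below 10⁻¹³ (typically 4–6 cycles, ~0.1 s at 2¹⁵ states).
* larger profiles containing stochastic members — power iteration to
  residual 10⁻¹³ (per-round randomization makes these chains fast-mixing).

Payoffs, cooperation rates and the full-cooperation probability are
expectations of newest-column functionals under the stationary vector.
"Probability of full cooperation" means the stationary probability that the
newest round is unanimous cooperation (not the expected cooperator
fraction).  ε = 0 is deliberately rejected by the stationary solver (the
chain is then reducible); error-free questions are answered by the
recurrent-class and replay machinery instead.

## Certification

**Defensibility.**  Because PG payoff differences count defections, a
co-player beats the focal strategy over some horizon iff the game graph —
nodes: focal (automaton) states; edges: the 2<sup>n−1</sup> co-player joint
choices with the focal action fixed by the strategy; weight for co-player
*j*: [*j* defects] − [focal defects] — contains a cycle of positive total
weight.  The strategy table is first minimized (Moore partition refinement;
CAPRI-2: 64 → 18 states, CAPRI-3: 32768 → 1446), which preserves all
output behavior and hence the verdict.  Positive cycles are found by
Bellman–Ford longest-path relaxation from a virtual super-source over all
nodes (any state may be initial), vectorized over the edge arrays, with
early exit on the first stationary sweep; on failure a predecessor walk
extracts a witness cycle, which a replay helper re-scores against the actual
table.  For co-player-symmetric strategies one co-player suffices; asymmetric
tables are checked per co-player.

**Efficiency.**  Two diagnostics must agree: (1) the full-cooperation
probability of the homogeneous population approaches 1 along the error grid
{10⁻³, 10⁻⁴, 10⁻⁵}, operationalized as the residual 1 − *p* shrinking at
least 5× per decade (the observed behavior is ~10×, i.e. linear in ε);
(2) whenever full defection is also recurrent under error-free play, the
minimum number of mistaken actions needed to leave full cooperation strictly
exceeds the number needed to regain it.  Resistances are Dijkstra shortest
paths in the joint-history graph with edge cost = number of players deviating
from prescription, terminating in the target's error-free basin.  For
CAPRI-n the recurrent classes are exactly the two fixed points (all-c,
all-d) and the resistances are *n* vs *n* − 1.

**Distinguishability.**  In the profile (Ω, AllC, …, AllC), the focal-minus-
AllC payoff gap is computed along the error grid and extrapolated linearly to
ε → 0; the verdict requires a limit above 10⁻³ payoff units (well above
solver tolerance, far below any genuine O(1) exploitation gap — CAPRI-2's
gap is 0.46, CAPRI-3's 0.91, TFT's extrapolates to 2 × 10⁻⁹).

## Evolutionary dynamics

Low-mutation Moran process with Fermi imitation at selection strength σ.
Group payoffs at mutant count *j* are hypergeometric averages over co-players
drawn without replacement — for *n* = 3 the binomial-coefficient weights are
normalized by C(N−1, 2), the number of unordered co-player pairs (validated
against a brute-force enumeration oracle).  Fixation probabilities use the
standard product form φ⁻¹ = Σ<sub>i</sub> ∏<sub>j≤i</sub> Γ<sub>j</sub>,
Γ<sub>j</sub> = exp[σ(s<sub>y</sub> − s<sub>x</sub>)], accumulated in the
log domain (finite at large σN); for *n* = 2 the explicit single-sum closed
form is also exposed and agrees to ≤ 10⁻¹² — an algebraic-identity oracle in
the tests.  Abundances are the stationary vector of the embedded jump chain
T[y → x] = φ<sub>xy</sub>/(K−1).  Payoff tables cache each profile's
stationary newest-joint-action distribution, so a (b, N) sweep costs one
chain solve per profile plus a dot product per benefit value.  Random-mutant
experiments sample unconstrained uniform tables by default (co-player-
symmetric sampling behind a flag), with child RNG streams derived from one
seed.

## Monte Carlo

Numba-compiled kernels step the bit-packed joint history directly: a
rule-evaluated kernel for homogeneous CAPRI-n (no table; this is how
*n* = 4 with its 2²⁸ histories is handled), a lookup kernel for arbitrary
profiles with *n·m* ≤ 22, and a mixed kernel for CAPRI against memory-one
stochastic co-players.  Trajectories start from the all-cooperate prehistory
(the stationary law at ε > 0 is initial-condition-free, but see the
metastability caveat), discard a 10⁴-round burn-in, and report batch-means
standard errors over 100 batches.  Deterministic table entries skip the
intent draw so the rule and lookup kernels consume identical RNG streams —
same seed, same trajectory, bit-identical results.

## Metastability: what finite trajectories can and cannot show

At ε = 10⁻⁴ the homogeneous CAPRI-n chain concentrates on two phases.  The
exact chains show that 1 − *p*(full cooperation) decomposes into a
recovery-overhead part (~2·*n*ε: each error costs two non-unanimous rounds)
plus the mass of the defective phase: 4.0 × 10⁻⁴ of the 8.0 × 10⁻⁴ total at
*n* = 2, and 2.7 × 10⁻³ of 3.3 × 10⁻³ at *n* = 3.  The phases exchange at
rates O(ε<sup>n</sup>) (fall) and *n*ε<sup>n−1</sup> (escape), so their mass
ratio scales ∝ ε with a prefactor that grows quickly with *n* — measured at
*n* = 4 via simulation at ε ∈ {10⁻², 3 × 10⁻³} (where both phases recur),
the fall prefactor is ~10³, putting the defective-phase mass near 0.02 at
ε = 10⁻⁴ and the stationary full-cooperation probability near 0.98.  A
trajectory of 10⁷ rounds, however, waits ~10¹³ rounds for its first fall:
started from cooperation it honestly measures the cooperative phase alone
(0.9992 ± 0.00001 at *n* = 4) and its batch-means error bars cannot cover
the stationary value.  Consequently the simulator is cross-validated against
the exact chains only where the trajectory genuinely mixes within the run
(n = 2 at ε ∈ {10⁻², 10⁻³}, n = 3 at 10⁻²), and the four-player stationary
cooperation probability should be regarded as accessible to exact or
rare-event methods, not to direct simulation.  The same finite-ε reasoning
bounds evolutionary robustness: φ ≤ 1/N is exact in the ε → 0 limit, while
at ε = 10⁻⁴ a handful of efficient, CAPRI-tolerant mutants (win-stay-
lose-shift-like tables whose self-play cost is ε rather than CAPRI's 6ε)
reach φ = 1/N + O(σε) (0.10005 at N = 10, shrinking proportionally to ε).

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| ε | 10⁻⁴ | implementation-error rate (evolution, certification reference point) |
| error grid | 10⁻³, 10⁻⁴, 10⁻⁵ | efficiency/distinguishability diagnostics |
| b, N, σ | 3, 30, 1 | donation benefit, population size, selection strength for abundance experiments |
| b = 2, N = 10 | — | mutant-invasion experiments |
| rounds, burn-in | 10⁷, 10⁴ | trajectory simulation |
| IAD residual | 10⁻¹³ | stationary-solve stopping rule (∞-norm) |
| distinguishability threshold | 10⁻³ | extrapolated gap counted as strictly positive |
| efficiency shrink factor | 5× / decade | required decay of 1 − p along the error grid |

## Known limitations

* Exact chains are materialized for *n* ≤ 3 (2¹⁵ states); *n* = 4 is
  simulation-only, with the metastability caveat above.  *n* ≥ 5 is out of
  scope.
* Defensibility certification requires a materialized table (use the
  automaton route); rule-evaluated CAPRI-4 is not certified, only simulated.
* Stochastic strategies are supported as memory-one profile members, not as
  certifiable focal strategies.
* The evolutionary layer covers the two- and three-player group samplings;
  discounting, finite mutation rates, and structured populations are out of
  scope.
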