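# Methods

## Model

The simulator implements a three-population replicator system on the unit
cube. Populations: private operators (share `x` provides high-quality
service), government agents (share `y` regulates actively), the public
(share `z` participates in monitoring). A 2×2×2 stage game assigns each
pure outcome a payoff triple from 17 non-negative scalars, all measured in
one common dimensionless utility unit — monetary amounts and "reputation
levels" are added freely, which is a modelling assumption, not an
accounting identity.

Stage-game conventions (implemented literally in `build_payoff_table`):

- the subsidy `We` is paid only for compliant operation;
- the fine `Ws` moves from operator to government only when a violation
  occurs **under supervision** — a violation reported by the public alone
  costs the operator nothing;
- the exposure penalty `Fg` hits the government only in the (violation, no
  supervision, participation) cell;
- reputation terms `alpha*`/`beta*` enter only when the public
  participates;
- a participating public is always paid `Rp` (even by a non-regulating
  government), and damaged members receive compensation `P` that is not
  debited from any other player.

The last two conventions are deliberate literalisms: they are how the
payoff table is defined, even though one could argue a different accounting.
Changing them changes the dynamics; the package treats the table as the
ground truth and verifies the closed forms against it (see Testing).

Expected payoffs per strategy are the table cells weighted by the other two
populations' mixed strategies; replicator rates are
`share · (own-strategy payoff − population mean)`, which factor into the
closed forms

```
dx/dt = x(x-1)·G,  G = CH - CL - We - z(α1-α2) - y·Ws
dy/dt = y(y-1)·J,  J = Cg - Rg - z(β1-β2) - (1-x)z·Fg - (1-x)·Ws
dz/dt = z(z-1)·D,  D = Cp - Rp - P + P·x
```

`Mi`, `Fi` and `R1` shift whole payoff rows equally and cancel from every
difference: the dynamics are bitwise invariant to them. They exist only for
payoff-table display and default to arbitrary positives (100, 100, 50).

Critical thresholds (`y*` where `G(y*)=0` given `z`; `z*` where `J(z*)=0`
given `x`; `x*` where `D(x*)=0`) are returned **unclipped** with an
in-range flag: a threshold outside [0,1] is meaningful — it says the drift
direction is fixed over the whole feasible interval. Under the reference
calibration `x* = 305/300 > 1`, so `D < 0` everywhere and the public always
converges to monitoring.

## Stability classification

The Jacobian's off-diagonal entries all carry `s(s-1)` prefactors, so at
each of the 8 corner fixed points the matrix is diagonal and the
eigenvalues are `(2x-1)G`, `(2y-1)J`, `(2z-1)D`. `classify_equilibrium`
uses a zero-tolerance `tol` (default 1e-9): **ESS** if all eigenvalues
< −tol, **unstable** if any > +tol, **non-hyperbolic** otherwise; a
separate boolean flags any eigenvalue within tol of zero even when a
positive one already settles instability. The default tolerance matters:
the reference calibration places an exact zero at two corners
((0,0,1) and (1,0,1)), which are reported unstable *and* non-hyperbolic.

The symbolic per-corner eigenvalue expressions are kept in the reference
table's own printed order, which varies row to row; the returned component
permutation maps them back to (x, y, z) order so symbolic and numeric routes
are compared entry-for-entry, not as multisets. Interior (mixed) rest
points are not enumerated; `interior_equilibrium` offers an optional
numeric root-finder but it is not part of the validated surface.

## Reference calibration

`baseline_parameters()`: `Cp=10, Rp=15, β1=30, β2=5, Cg=30, Rg=20, α1=20,
α2=10, CH=70, CL=30, We=30, Ws=80, Fg=100, P=300` (and the three
dynamics-neutral defaults above). Under it the all-cooperate corner (1,1,1)
is the unique ESS with eigenvalues (−5, −15, −80) in the (public,
government, private) directions, and every interior start converges there.

## Numerical integration

`solve_ivp` RK45, `rtol=1e-8`, `atol=1e-10`, default horizon 50 time units,
2001 output samples plus the dense interpolant. Time units are abstract —
the model defines no calendar — so convergence times are ordinal: valid for
comparing runs, not for forecasting. The vector field is tangent to the
cube, so clamping stored states to [0,1] only corrects round-off; observed
solver wobble on the plateau near a fixed point is of order 1e-8, which is
why trajectory-monotonicity checks use a 1e-6 slack. Convergence times are
entry times into a band (default: tracked share within `eps=0.01` of 1,
required to stay there), refined below the sampling grid by root-bracketing
on the dense interpolant; the 0.01 band is tight enough to order sweep
curves and loose enough to be robust to solver tolerance.

The default initial state for sweeps and demos is (0.2, 0.2, 0.2); nothing
canonical fixes it, and all qualitative conclusions below were checked to
be init-independent on an interior grid, except where noted.

## Sensitivity sweeps

Six built-in grids: `We ∈ {30,50,70}` and `Ws ∈ {40,80,120}` tracking `x`;
`Cg ∈ {30,45,60}` and `Rg ∈ {20,40,60}` tracking `y`; `Cp ∈ {5,10,15}` and
`Rp ∈ {10,15,20}` tracking `z`. The Cp/Rp grids are our choice, symmetric
around the calibration values, since no canonical grid exists for them.

`monotonicity_report` orders convergence times across a grid. A run whose
tracked share never settles gets time +∞. A grid is **indistinguishable**
when all times are finite and none deviates from the median by more than 5%
of the median — the criterion under which the public-side grids (whose
initial drift is dominated by the `P(1-x)` term, ~240 units, against which
the swept `Rp−Cp ∈ [0,10]` is noise) report no visible effect.

### A genuine inconsistency in the Cg grid

The (1,1,1) corner is stable in the government direction only when
`Cg − Rg < β1 − β2`, i.e. `Cg < 45` at the calibration. The conventional
sweep grid `{30, 45, 60}` crosses that boundary: integrating from
(0.2,0.2,0.2), `y` plateaus at ≈0.976 for `Cg=45` (marginal case) and
collapses to 0 for `Cg=60`. "Time for `y` to reach 0.99" is therefore
finite only for `Cg=30`, and the expected strict slower-with-higher-cost
ordering cannot hold on this grid — the sweep verdict is honestly
"non-monotone" (one finite time, two infinite). The package keeps the grid
and reports the truth; narrowing the grid to the stable region would hide
the boundary, which is itself the scientifically interesting object
(`test_verdict_flips_exactly_at_the_critical_value` pins it at Cg = 45).

## Synthetic inputs

`sample_parameters` draws each parameter uniformly on [0.5×, 2×] its
calibration value (configurable) and rejects draws violating the requested
regime: `ess_stable` (all three ESS margins negative), `ess_violated`
(exactly one chosen margin positive), or `unconstrained` (only the
structural inequalities `CH>CL`, `α1>α2`, `β1>β2`). Budget 10,000 attempts,
then an error naming the infeasible constraint. All sampling is a pure
function of the seed. The generator emulates parameter *regimes*, not
empirical data: no real PPP project informs the ranges, so passing tests
demonstrate internal consistency and qualitative behaviour of the model,
not calibration to observed projects.

## Testing strategy

Every closed form is checked against an independent route: replicator rates
against the payoff-table oracle (1e-9 over random draws), the analytic
Jacobian against central finite differences, the symbolic corner-eigenvalue
rows against the numeric diagonal and against a general eigensolver, and
threshold values against direct root evaluation (1e-12). Dynamics tests
check cube invariance, corner fixity, segment monotonicity under a negative
switching function, and determinism of ensembles.

## Known limitations

- Deterministic infinite-population replicator only; no finite-population
  or stochastic (Moran) dynamics.
- Two strategies per player, three players; no Bayesian or
  asymmetric-information extensions.
- No Lyapunov construction or analytic basin-of-attraction results; global
  convergence under the calibration is an empirical grid observation.
- Convergence times are unit-free ordinals.
- The stage-game accounting questions noted above (who funds `P`; `Rp` paid
  by a non-regulating government) are resolved by fiat of the payoff table.
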