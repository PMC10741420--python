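# Methods

## Model

Nucleosomal DNA is modelled as closed circular DNA — a knot — because
histone H1 pins the entry/exit points. Its topology is the triple
(Lk, Wr, Tw) with Lk = Wr + Tw (White's formula), Lk = N/nᵢ from the
base-pair count, and Wr the signed superhelical wrap (left-handed
negative). The elastic free energy of a conformation is a gradient
Landau expansion in the two-component order parameter
Ψ = (cos(θ/2)e^{−i(ϕ+χ)/2}, sin(θ/2)e^{i(ϕ−χ)/2}) of the Euler angles
of the helix-axis frame, which reduces to

    F = (B/2)[θ′² + ϕ′² sin²θ] + (C/2)[ϕ′ cosθ + χ′]²,

i.e. bending rigidity times squared curvature plus torsional rigidity
times squared torsion τ = ϕ′cosθ + χ′. Integrating τ/2π along the
molecule returns the twist number, which closes the loop back to the
topological bookkeeping.

The torus-knot (Hopfion) reduction maps the knot onto a torus with
toroidal winding P and poloidal winding Q, Hopf charge W = PQ identified
with Lk, through θ = 2R, ϕ = Pφ + QΘ, χ = Pφ − QΘ. With dR/ds = 0 and
constant rates m = dφ/ds, n = dΘ/ds, the density becomes the closed form

    F(P) = (B/2)(Pm + (W/P)n)² sin²(2R) + 2C(Pm cos²R − (W/P)n sin²R)².

**Sign of the torsion factor.** Expanding the torsional part of the
mapped density produces the cross term −2PQ m n sin²(2R), which forces
the relative minus sign between Pm cos²R and (W/P)n sin²R. The package
treats the composition identity — closed form ≡ Euler-angle density
evaluated on the mapped derivatives (θ′ = 0, ϕ′ = Pm + Qn,
χ′ = Pm − Qn) — as the central correctness property and tests it on
randomly drawn configurations to 1e-9 relative.

The B–Z transition module evaluates the tilted quartic double well
V_eff(ρ) = V₀[(ρ/ω₀)² − 1]² − (τ − τ_c)ρ over the inter-base-pair
rotation ρ (rad/bp, positive = right-handed). Its stationary points are
the real roots of the depressed cubic ρ³ − ω₀²ρ − (τ−τ_c)ω₀⁴/(4V₀) = 0,
solved in closed form (trigonometric branch for three real roots,
Cardano for one; `numpy.roots` as a fallback on degenerate arithmetic)
and classified by the sign of V″.

## Parameters and units

| parameter | default | meaning |
|---|---|---|
| nᵢ | 10.5 bp/turn | B-DNA helical repeat; Lk = N/nᵢ, ω₀ = 2π/nᵢ ≈ 0.6 rad/bp |
| l_p | 50 nm | bending persistence length; B = l_p·k_BT = 2.07×10⁻¹⁹ J·nm at 300 K |
| l_t | 95 nm | torsional persistence length; C = l_t·k_BT = 3.933×10⁻¹⁹ J·nm |
| T | 300 K | temperature; k_B fixed at 1.38×10⁻²³ J/K |
| R | 20° (canonical) | torus bending angle, θ = 2R; open interval (0°, 90°) |
| m, n | 1 | toroidal/poloidal advance rates dφ/ds, dΘ/ds, reduced units |
| V₀, τ_c | 6×10⁻²¹ J, −7.9×10⁻²¹ J | double-well scale and critical torque |

Two unit systems are kept explicitly. Energies default to *reduced*
units — k_BT per unit arc length, in which B = 50 and C = 95 numerically
equal the persistence lengths — because the headline minima (≈938, ≈1071
per unit length b) live in these units; `ElasticConstants.to_si` converts
to joules. k_B is fixed at the conventional two-significant-figure value
so the derived SI rigidities match their standard printed forms exactly.

Sign conventions are centralised: writhe is signed (left-handed wrap
negative) on the topology side; the energy side uses magnitudes — P is
the magnitude of the wrap number, and the bending angle uses |Wr|
(θ = 40° comes from 1.75, not −1.75).

## Numerical choices

- **Profile scans.** F(P) is evaluated on P ∈ [0.5, W] at step 0.1 by
  default — the resolution at which the canonical argmins 1.9/2.1 are
  defined — with Q = W/P continuous. The grid minimum is then refined by
  bounded scalar minimization (Brent, xatol 1e-8) on the interval
  bracketing the best grid point; both grid and refined results are
  reported, and the refinement is clamped never to exceed the grid
  minimum. The continuous relaxation is deliberate: non-integer P values
  such as 1.75 or 2.1 are physically meaningful scan points even though
  the strict torus-knot states have integer (P, Q); `integer_minimum`
  provides the integer-restricted variant (ties break toward smaller P).
- **Quadrature.** Twist numbers use trapezoidal quadrature on the
  caller's grid, with no hidden resampling; convergence is second order
  in the spacing and is tested as such. Missing Euler-angle derivatives
  are filled by second-order central differences.
- **Domain guards.** θ must stay in the open interval (0, π) (tolerance
  1e-9 at the endpoints) because the Euler frame is degenerate at the
  poles; the exact pole limits are exercised only through the closed-form
  limit expressions. R is restricted to (0°, 90°); the R → 0/90 limits
  2C(Pm)² and 2C(Qn)² are available as tested asymptotics. Lk is kept
  exact as a real number, with an integer accessor that errors if the
  residual exceeds 1e-9.
- **Determinism.** Nothing in the tool is stochastic; CLI runs are
  byte-reproducible. CSV output is RFC-4180 with 12 significant digits.

## Scope and limitations

- The model evaluates the free-energy functional on the torus-knot
  family; it does not solve the Euler–Lagrange equations of the general
  functional, compute Wr/Tw from 3-D space curves (Gauss integrals), or
  model histone–DNA binding energetics, sequence/salt-dependent
  elasticity, or B–Z transition kinetics.
- The rates m, n have no firmly established physical values; m = n = 1
  (equal toroidal and poloidal advance) is the working default and both
  remain free parameters.
- The arc-length unit of the reduced system is implicit; total energies
  are reported per unit reduced length b (E = F·b, exact because F is
  s-independent under constant R, m, n).
- Preset scenarios (147/63/168/189 bp; R variants 5°–30°) encode the
  standard nucleosome constructs; they are parameter sets, not fits to
  structural data.
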