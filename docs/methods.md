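# Methods

## The inference model (LMFI)

Let X ∈ ℝ^{m×n} be additive-coded genotypes (AA/Aa/aa → 0/1/2) and Y ∈ ℝ^{m×K}
the phenotypes. For each phenotype k a boosting model provides nonnegative
feature importances F_k ∈ ℝ^n_{≥0}; the inner model is fitted on the scaled
matrix X·diag(F_k):

* continuous: M̂_k minimizes ‖X·diag(F_k)·M − y_k − w_{0k}‖² + λ‖M‖²,
* binary: penalized logistic regression with the standard sigmoid
  p = 1/(1+exp(−t)), oriented so larger scores mean class 1.

The importance is folded into the published weights, W_k = F_k ∘ M̂_k, which
makes the algebraic identity X·W_k = (X·diag(F_k))·M̂_k exact: the encrypted
evaluator only ever needs the raw genotype matrix and one weight vector per
phenotype. Wherever F_k[j] = 0 the folded weight is exactly zero.

Choices and defaults:

* **Importance provider** — XGBoost gain importance (`n_estimators=60,
  max_depth=3`), AdaBoost, or a dependency-free |Pearson correlation|
  fallback that keeps the pipeline testable without boosting. Which provider
  (and which hyper-parameters) is best is data-dependent and left
  configurable; the choice only changes the plaintext model, never the
  encrypted evaluation.
* **Ridge penalty** — λ = 10⁻³·m by default (stabilizes n ≫ m fits),
  configurable including 0, in which case the continuous fit is exact least
  squares and noiseless data is recovered to machine precision.
* **Binary scoring** — AUC is computed on decrypted *linear* scores; the
  sigmoid is rank-preserving, so evaluating it homomorphically would change
  nothing and is not attempted.

## CKKS parameters and level budget

The scheme is leveled CKKS over Z_q[X]/(X^N+1) in full RNS form.

| parameter | default | notes |
|---|---|---|
| ring degree N | 8192 | N/2 = 4096 complex slots |
| modulus chain | three 60-bit primes ≡ 1 (mod 2N) | last prime is the key-switching (special) prime |
| scale Δ | 2⁴⁵ | see noise budget below |
| secret | uniform ternary {−1,0,1} | |
| noise | discrete Gaussian, σ = 3.2 | |

The inference circuit has multiplicative depth 1 (one Hadamard product plus
one rescale), so two data primes and one special prime suffice: a fresh
ciphertext sits at the two-prime level, the single rescale drops one, and a
second rescale raises an error.

**Noise budget and the choice Δ = 2⁴⁵.** With a 60-bit rescale prime the
post-rescale scale is Δ²/q₁. Rescale rounding noise is ≈ √(N/18)·√N ≈ 2¹¹ in
slot units at N = 8192; at Δ = 2⁴⁰ the residual scale 2²⁰ would leave only
~10⁻³ relative precision, while Δ = 2⁴⁵ leaves ~10⁻⁶ — comfortably inside
every stated tolerance. Matrix diagonals are encoded at scale q₁ (the prime
the final rescale drops), so the evaluation output lands *exactly* at the
vector scale Δ and intercept addition needs no scale juggling.

**Key switching** is hybrid RNS: digits are the centred per-prime residues
of the switched polynomial, switching keys are raised by the special prime
P, and the product is divided by P with rounding. This divides the
key-switching noise by ~2⁶⁰ and makes rotations safe even on fresh
ciphertexts at scale Δ. All rotations and relinearizations of the depth-1
circuit happen at the top level, and key switching is only supported there.

**Arithmetic.** Residues are uint64 numpy arrays; modular products are exact
Montgomery multiplication via 32-bit limb splitting, and polynomial products
use the negacyclic number-theoretic transform (Cooley–Tukey forward,
Gentleman–Sande inverse, 2N-th root powers folded in). The NTT layer is
validated against a big-integer schoolbook convolution oracle. Encoding uses
the canonical embedding: slot j of a polynomial a is a(ζ^{5^j}); the
implementation evaluates it via one FFT by mapping slot j to DFT bin
(5^j−1)/2 mod N. Vectors shorter than N/2 are zero-padded by `encode`;
self-repeating layouts (weight slices, diagonals) are tiled explicitly by
the callers that rely on the repeat-decoding property.

Small-N test parameters (N = 64, three 45-bit primes, Δ = 2³³) run every
code path in milliseconds with the same noise-budget shape.

## Packing and the BSGS evaluation

An l×n matrix with l | n (both powers of two) is represented by its l tiled
generalized diagonals m_j[r] = M[r mod l, (r+j) mod n] — tiling repeats the
matrix itself, so no zero rows are introduced — giving
M·z = fold(Σ_j m_j ∘ (z ≪ j)). The baby-step–giant-step regrouping

Σ_j m_j ∘ (z ≪ j) = Σ_{i1} ( Σ_{i2} (m_{i1·g+i2} ≫ i1·g) ∘ (z ≪ i2) ) ≪ i1·g

with l = g·b reduces encrypted rotations from l to g + b; the inner
pre-rotations ≫ i1·g are applied to plaintext diagonals before encoding,
where they are free. g is the smallest power of two ≥ √l (b = l/g), the
unique choice reproducing the reference 16 + 8 rotation split at l = 128.
The final γ = log₂(n/l) fold steps rotate by l·2^{j−1} and add, summing the
n/l column blocks.

Wider matrices are split into s = ⌈n/(N/2)⌉ submatrices; the per-submatrix
inner sums are accumulated *before* the giant-step and fold rotations, so
those rotations are executed once rather than s times. Adjacent sample rows
are packed as real/imaginary parts of complex rows, halving l (and hence
ciphertexts and multiplications); the client unpacks slot r into samples 2r
and 2r+1 after decryption. Intercepts are encrypted as the constant
w₀·(1+i) under complex packing so both packed rows receive the shift.

**Operation accounting.** `count_ops` reports the shared-rotation convention
(g + b + γ rotations, independent of s), which is how the reference counts
(640 multiplications, 29 rotations for 198×20390 at N = 8192) are stated.
The executed counts differ in one place: each of the s encrypted sub-vectors
is baby-rotated separately (s·(g−1) executed rotations), and the audit log
reports executed counts without claiming they match the shared convention.

**Relinearization.** In encrypted-matrix mode the ciphertext–ciphertext
products are kept as lazy three-component sums; all submatrices and baby
steps of one giant-step group are summed first and relinearized once. One
relinearization per giant-step group is the minimum: each group must be
reduced to two components before its own Galois rotation, since terms under
different rotation images of s² cannot be summed. The relinearization count
is therefore b per evaluation — independent of s and of g, and exactly one
for shapes with a single giant step.

## Protocol and trust boundary

Client, Modeler and Evaluator are simulated as functions exchanging files in
a session directory (`public/`, `client/`, `evaluator/`, `predictions/`); no
network layer. The evaluator reconstructs its key bundle from broadcast
artifacts only and its code path takes no secret-key input; tests scan every
non-client artifact for the secret-key container tag. All artifacts embed a
16-hex-digit parameter digest and loading rejects mismatches. Containers are
versioned binary: magic, version, digest, type tag, little-endian 64-bit
residue arrays; round trips are bit-exact, and fixed seeds give
byte-identical keys and ciphertexts.

## Synthetic data

The generator emulates the target study's shape: genotypes are
Binomial(2, p_j) with p_j ~ U(0.05, 0.5) (Hardy–Weinberg, no linkage),
continuous phenotypes are sparse linear signals X·β + w₀ + ε (20 causal
variants, N(0, 0.5²) effects, ε ~ N(0, 0.05²)), binary phenotypes are
Bernoulli(sigmoid(X·β + w₀)) with the intercept redrawn until both classes
appear. The default demo scale is m = 300, n = 2048, K = 5 (3 continuous +
2 binary), which a full secure session processes in well under a minute at
N = 8192 on one CPU; the 198×20390 production shape is exercised by the
planner, which needs no ciphertext arithmetic.

What passing tests show — and what they do not: the generator has no linkage
disequilibrium, population structure, relatedness or epistasis, so results
say nothing about model *accuracy* on real cohorts. What the synthetic
pipeline does establish is exactness of the cryptographic path: decrypted
secure predictions match the plaintext pipeline to ~10⁻⁷, so any accuracy
attainable in plaintext carries over unchanged under encryption.

## Numerical and degenerate-input choices

* NRMSE divides by the range of the *true* values; constant truth is an
  error, as is single-class AUC and a constant training target.
* AUC ties count ½ (Mann–Whitney convention).
* All-zero importance is an error in the fit functions; the trainer falls
  back to uniform importance if a boosting provider returns all zeros.
* Rotation by 0 is the identity (no key needed); a missing Galois key is an
  error, never a silent fallback. Clients generate exactly the key set the
  plan declares.
* Scales are compared with 10⁻⁹ relative tolerance; RNS rescaling always
  divides by the top active prime, so the rescale API takes no divisor
  argument.

## Known limitations

* No bootstrapping, slot conjugation, or circuits deeper than 1.
* Security parameters are taken from the evaluated configuration and the
  usual HE recommendations; no lattice-security estimation is performed, and
  there is no side-channel hardening. Keys and ciphertexts are handled as
  ordinary files.
* Key switching (hence rotation/relinearization) only at the top level —
  sufficient for this protocol, not a general-purpose CKKS library.
* The honest-but-curious model of the protocol is assumed; there is no
  malicious-security hardening, authentication or transport layer.
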