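# ciphergeno

Privacy-preserving genotype→phenotype inference with encrypted linear models.

Genotype and phenotype data are sensitive, yet outsourced phenotype
prediction is useful: a *client* holds genotype test data, a *modeler* holds
a trained model, and an untrusted *evaluator* should compute predictions
without seeing either. `ciphergeno` implements that protocol end to end:

1. **Plaintext training (LMFI).** For each phenotype k, a boosting model
   (XGBoost by default) supplies nonnegative feature importances F_k; a
   ridge-penalized linear regression (continuous phenotypes) or logistic
   regression (binary) is fitted on the importance-scaled genotypes
   X·diag(F_k), and the scaling is folded into the published weights,
   W_k = F_k ∘ M̂_k, so inference is a plain linear score
   Ŷ_k = X·W_k + w_{0k}.
2. **Encryption (CKKS).** A self-contained leveled CKKS implementation over
   Z_q[X]/(X^N+1): canonical-embedding encoding, RLWE keys, slot-wise
   add/multiply, Galois rotations, hybrid RNS key switching and rescaling.
   Defaults follow the evaluated configuration: N = 8192, three 60-bit
   primes, scale Δ = 2⁴⁵, ternary secret, σ = 3.2 Gaussian noise.
3. **Encrypted matrix–vector products.** The genotype matrix is zero-padded
   to power-of-two shape, split into ≤ N/2-column submatrices, adjacent
   sample rows are packed into complex slots, and the tiled generalized
   diagonals m_j[r] = M[r mod l, (r+j) mod n] are pre-rotated and encrypted.
   The evaluator computes M·z with the baby-step–giant-step schedule
   (l = g·b Hadamard products, only g + b + log₂(n/l) rotations), summing
   submatrix partials before rotations and lazy ciphertext products before
   relinearization.
4. **Scoring.** The client decrypts, unpacks complex slots back to sample
   order and computes S_k = 1−NRMSE (continuous) or AUC (binary), and their
   mean S̄.

For the reference 198-sample × 20 390-variant workload at N = 8192 the
planner produces 5 submatrices (last chunk 4006 columns, each padded to
256×4096 and packed to 128×4096 complex), 5×128 = 640 encrypted diagonals
and homomorphic multiplications, and a shared rotation budget of
16 + 8 + 5 = 29.

## Worked example

A complete in-process session on a small synthetic dataset (16 samples, 48
variants, two continuous and one binary phenotype) at the small test
parameters (N = 64):

```python
import numpy as np
from ciphergeno import (small_test_params, gen_dataset, train, predict_plain,
                        run_secure_session, score_predictions)

ds = gen_dataset(m=16, n=48, kinds=("continuous", "continuous", "binary"),
                 n_causal=8, seed=42)
model = train(ds.X, ds.phenotypes.to_numpy(), ds.kinds,
              method="correlation", seed=0)
scores, audit = run_secure_session(small_test_params(), ds.X, model, seed=1)
plain = predict_plain(ds.X, model)
rep = score_predictions(ds.kinds, ds.phenotypes.to_numpy(), scores)
print("max |secure - plain| =", np.max(np.abs(scores - plain)))
print("S_k =", [round(s, 4) for s in rep.scores])
print("S_bar =", round(rep.average, 4))
print("ops:", audit.op_counts)
```

prints

```
max |secure - plain| = 2.666553329255805e-07
S_k = [0.9984, 0.9924, 1.0]
S_bar = 0.9969
ops: {'rotation': 27, 'mult': 48, 'relin': 6, 'rescale': 3}
```

The decrypted secure predictions agree with the plaintext pipeline to
~3·10⁻⁷; the per-phenotype accuracies (two 1−NRMSE values and one AUC) and
their average are computed from those decrypted scores. The audit lists the
homomorphic operations the evaluator actually executed.

The same flow is available from the shell via directory hand-offs between
the three parties:

```sh
ciphergeno simulate -m 300 -n 2048 --seed 0 --out demo
ciphergeno train --geno demo.geno.tsv --pheno demo.pheno.tsv --out demo.model.json
ciphergeno keygen --session sess -m 300 -n 2048 --seed 1
ciphergeno encrypt-data  --session sess --geno demo.geno.tsv
ciphergeno encrypt-model --session sess --model demo.model.json
ciphergeno evaluate --session sess          # evaluator: no secret key
ciphergeno decrypt --session sess --out demo.scores.tsv
ciphergeno score --scores demo.scores.tsv --pheno demo.pheno.tsv
ciphergeno plan -m 198 -n 20390             # packing/op-count planner
```

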