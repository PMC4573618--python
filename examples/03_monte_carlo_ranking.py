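"""Rank transcription factors by TFCV on a small known-truth problem.

toy_matrices builds an indicator matrix C, an affinity matrix D and an
expression-change vector Z = C.D.x + noise with the true functional levels x
nonzero only for the first two PWMs. The Monte-Carlo subset regression
samples random groups of n_t PWMs, fits each by least squares, and credits
every sampled PWM with 1/Err^2; PWMs that genuinely explain Z accumulate the
largest TFCV and their cumulative TFL carries the sign of their effect.
"""

from dhstf import design_matrix, rank_tfs, run_monte_carlo, toy_matrices

C, D, Z, truth = toy_matrices(n_genes=40, n_dhs=50, n_pwms=10, seed=7,
                              n_planted=2, noise_sd=0.1)
A = design_matrix(C, D)
table = run_monte_carlo(A, Z, n_t=3, n_iter=50_000, seed=1)
ranked = rank_tfs(table, top_n=5)

print("true functional levels:",
      {f"M{j + 1:05d}": round(float(x), 3) for j, x in enumerate(truth["x_true"]) if x})
print(ranked.to_string(index=False))

# The two planted PWMs head the TFCV ranking and their TFL signs match the
# planted effect signs; decoy PWMs trail with much smaller TFCV.
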