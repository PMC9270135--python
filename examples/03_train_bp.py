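"""Train the plain backpropagation network on a synthetic cohort.

Generates a cohort, min-max scales the features on the training split,
trains the 5-10-1 sigmoid network by full-batch gradient descent (learning
rate 0.2, error goal 0.001), and prints the evaluation table: one row per
held-out patient with expected vs model output and absolute error.
"""

from melasma_gabp import (
    CohortSpec,
    NetworkConfig,
    evaluate,
    fit_normalizer,
    generate_cohort,
    split_cohort,
    train,
)
from melasma_gabp.cohort import to_arrays

spec = CohortSpec(seed=7)
records = generate_cohort(spec)
train_recs, test_recs = split_cohort(records, spec)
X_train, y_train = to_arrays(train_recs)
X_test, y_test = to_arrays(test_recs)

normalizer = fit_normalizer(X_train)
config = NetworkConfig(seed=7)  # 5 inputs, 10 hidden (m+n+a, a=4), 1 output
result = train(config, (normalizer.transform(X_train), y_train))

print(f"trained {config.n_input}-{config.hidden}-{config.n_output} network: "
      f"{result.epochs_run} epochs, final training error {result.error_history[-1]:.5f}, "
      f"converged={result.converged}")
# The training error is the mean over samples of 1/2*(target - output)^2;
# convergence means it reached the 0.001 goal before the epoch cap.

report = evaluate(result.final_weights, normalizer, (X_test, y_test),
                  sample_ids=[r.id for r in test_recs])
print("\nfirst 10 test samples (expected vs model output):")
print(report.to_frame().head(10).to_string(index=False,
                                           float_format=lambda v: f"{v:.3f}"))
print(f"\nmean absolute test error: {report.mean_abs_error:.4f}")
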