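"""Train the two neural architectures: Bayesian-regularized MLP and LSTM.

The BRNN example shows the evidence framework at work: on a linear trait a
single purelin unit recovers the least-squares slope, and the effective
number of parameters stays close to what the data support. The LSTM example
chunks the marker vector into a genome-ordered sequence and fits the scalar
regression head with Adam.
"""

import numpy as np

from gwpred import (
    BrnnConfig,
    LstmConfig,
    predict_lstm,
    predict_net,
    simulate_genotypes,
    simulate_trait,
    train_brnn,
    train_lstm,
)

# --- BRNN: single linear unit on a noisy line ------------------------------
x = np.linspace(-1, 1, 60).reshape(-1, 1)
y_line = 2.0 * x.ravel() + np.random.default_rng(0).normal(0, 0.05, 60)
net = train_brnn(x, y_line, BrnnConfig(architecture=[(1, "purelin")], max_epochs=100, seed=0))
pred = predict_net(net, np.array([[0.0], [1.0]]))
print(f"BRNN learned slope {pred[1] - pred[0]:.3f} "
      f"(least squares: {np.polyfit(x.ravel(), y_line, 1)[0]:.3f})")
print(f"effective parameters gamma_eff = {net.trace['gamma_eff'][-1]:.2f} "
      f"of k = {net.n_weights} weights")

# --- LSTM: genomic regression on a heritable trait -------------------------
# a breeding-panel-like population: full-sib families and LD along chromosomes
G = simulate_genotypes(n=500, p=2000, ld_rho=0.6, n_families=50, offspring_per_family=10, seed=40)
y, truth = simulate_trait(G, n_qtl=10, h2a=0.5, seed=41)
perm = np.random.default_rng(42).permutation(500)  # keep families on both sides
train, test = perm[:450], perm[450:]
cfg = LstmConfig(hidden_units=32, state_activation="relu", minibatch_fraction=1.0,
                 chunk_size=100, epochs=30, seed=0)
lstm = train_lstm(G.dosage[train], y.value[train], cfg)
pa = np.corrcoef(y.value[test], predict_lstm(lstm, G.dosage[test]))[0, 1]
print(f"LSTM final training loss {lstm.loss_trace[-1]:.3f} "
      f"(scaled units), held-out predictive ability {pa:.3f}")
# gamma_eff near k would mean no smoothing; near 0 means the prior dominates.
# The LSTM's held-out correlation reflects both the trait's heritability and
# the family relatedness between training and test individuals.
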