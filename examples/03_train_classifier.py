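"""Train the LSTM-FCN deep classifier on simulated data and evaluate it.

A small end-to-end run (a few minutes on one CPU): simulate a balanced
white-noise dataset, train the two-branch network on the raw series, and
report held-out accuracy with the row-normalised confusion matrix.  Use the
desk-scale protocol constants for the full reproduction-quality run.
"""

import numpy as np

from tippingews import EWSNetConfig, TrainingConfig, build_dataset
from tippingews.experiments import confusion_matrix
from tippingews.nn.model import CLASS_ORDER, LSTMFCNClassifier, train_ewsnet

ds = build_dataset("W", n_per_class=25, seed=1)
net = EWSNetConfig(conv_filters=(32, 64, 32), conv_kernels=(8, 5, 3),
                   lstm_units=64, fc_sizes=(64, 3))
tc = TrainingConfig(epochs=40, batch_size=8, learning_rate=5e-4, seed=1)

model = LSTMFCNClassifier(net, seed=1)
history = train_ewsnet(model, [s.values for s in ds.train],
                       [s.label for s in ds.train], tc)
print(f"final epoch: loss {history['loss'][-1]:.3f}, "
      f"train acc {history['train_accuracy'][-1]:.3f}, "
      f"val acc {history['val_accuracy'][-1]:.3f}")

test = ds.test
probs = model.predict_proba([s.values for s in test])
pred = [CLASS_ORDER[i] for i in np.argmax(probs, axis=1)]
truth = [s.label for s in test]
acc = np.mean([p == t for p, t in zip(pred, truth)])
print(f"\nheld-out accuracy: {acc:.3f} on {len(test)} series")
print("confusion (rows = true C.T., S.T., N.T.):")
print(np.round(confusion_matrix(truth, pred), 3))
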