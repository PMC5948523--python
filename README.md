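# gramnas

Grammar-guided neuroevolution of convolutional/recurrent network topologies
for windowed multichannel sensor classification.

A BNF grammar describes the space of network topologies (input windowing,
1–5 convolutional layers, 1–3 feedforward/LSTM/GRU layers, optimizer and
learning rate). Integer-codon chromosomes are mapped to topologies by the
standard grammatical-evolution modulo rule, and a generational loop with
tournament selection, effective-region single-point crossover,
integer-flipping mutation, elitism, and similarity-based fitness sharing
searches that space. Candidate topologies are scored by a proxy fitness
(weighted F1 after 5 abbreviated training epochs, each on a fresh 5% sample
of the training windows); the best 20 phenotypes are archived in a hall of
fame, fully retrained (30 epochs), and combined into majority-voting
committees.

Networks are trained by a small self-contained numpy backend (time-axis 1-D
convolution, max-pooling, feedforward/LSTM/GRU layers with dropout and L1/L2
regularization, softmax head, and SGD/AdaGrad/AdaDelta/RMSProp/Adam/Adamax
learning rules), so no deep-learning framework is required.

## Layout

- `src/gramnas/grammar.py` — BNF parsing, codon→phenotype decoding,
  phenotype text serialization; default grammar in `src/gramnas/data/network.bnf`
- `src/gramnas/evolution.py` — GE loop, niching, hall of fame
- `src/gramnas/preprocess.py` — channel filtering, gap interpolation,
  min-max normalization, sliding-window tensors
- `src/gramnas/nn.py` / `src/gramnas/trainer.py` — numpy network backend,
  weighted F1, proxy fitness, full training
- `src/gramnas/ensemble.py` — majority voting, incremental committees,
  confusion matrices
- `src/gramnas/synth.py` — synthetic role-tagged sensor recordings
  (including a 113/16/119-channel fixture mirroring the published
  channel-role composition)
- `src/gramnas/cli.py` — `gramnas` command-line interface

## CLI

Each stage reads the previous stage's plain-text outputs; one `--seed` fans
out deterministically to all stages.

```bash
gramnas synth --out-dir run/data --seed 1 --n-timesteps 6000
gramnas preprocess --data run/data/data.dat --schema run/data/schema.tsv \
    --out-dir run/pre --window 24 --step 2
gramnas evolve --data run/data/data.dat --schema run/data/schema.tsv \
    --out-dir run/evo --seed 1            # add --grammar/--config to override
gramnas train-hof --data run/data/data.dat --schema run/data/schema.tsv \
    --hall-of-fame run/evo/hall_of_fame.json --out-dir run/models --seed 1
gramnas ensemble --data run/data/data.dat --schema run/data/schema.tsv \
    --models-dir run/models/models --out-dir run/report
```

`gramnas evolve --config cfg.yaml` accepts YAML overrides of the evolution
parameters (defaults: population 50, 100 generations, 30-generation stall,
tournament 3, crossover 0.7, mutation 0.015, 1 elite, codon size 256,
chromosome capacity 100, hall-of-fame size 20).

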