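{
 "version": 1,
 "worked_example": {
  "s1": "((.(.(...).).))",
  "s2": ".((.((...)).)).",
  "calibration": {
   "scale_min": 4.906890595608519,
   "scale_max": 39.25512476486815,
   "range_bits": 30.0,
   "derivation": "scale_min = log2(30), the analytic floor of C_LZ for a 30-bit trivial string; scale_max = max C_LZ over the binary encodings of all 2481 well-formed length-15 dot-bracket structures (hairpin loops >= 3)",
   "expected_k_scaled": 21.4
  }
 },
 "mealy_machine": {
  "n_states": 5,
  "input_alphabet": [
   "0",
   "1"
  ],
  "output_alphabet": [
   "0",
   "1"
  ],
  "next_state": [
   [
    1,
    4
   ],
   [
    3,
    0
   ],
   [
    1,
    4
   ],
   [
    2,
    0
   ],
   [
    3,
    3
   ]
  ],
  "output": [
   [
    1,
    0
   ],
   [
    0,
    1
   ],
   [
    0,
    1
   ],
   [
    0,
    0
   ],
   [
    0,
    0
   ]
  ],
  "start_state": 0,
  "seed": 0
 },
 "mealy_machine_trace": {
  "input": "0000000000",
  "states_visited": [
   0,
   1,
   3,
   2,
   1,
   3,
   2,
   1,
   3,
   2
  ],
  "output": "1000000000",
  "note": "traced by hand through the transition table: state 0 reads 0, emits 1, moves to 1; thereafter the cycle 1->3->2 emits 0s"
 },
 "perceptron_oracle_n2_k1": [
  {
   "weights": [
    -0.5,
    -0.5
   ],
   "bias": -0.5,
   "truth_table": "0000"
  },
  {
   "weights": [
    -0.5,
    -0.5
   ],
   "bias": 0.5,
   "truth_table": "1000"
  },
  {
   "weights": [
    -0.5,
    0.5
   ],
   "bias": -0.5,
   "truth_table": "0000"
  },
  {
   "weights": [
    -0.5,
    0.5
   ],
   "bias": 0.5,
   "truth_table": "1101"
  },
  {
   "weights": [
    0.5,
    -0.5
   ],
   "bias": -0.5,
   "truth_table": "0000"
  },
  {
   "weights": [
    0.5,
    -0.5
   ],
   "bias": 0.5,
   "truth_table": "1011"
  },
  {
   "weights": [
    0.5,
    0.5
   ],
   "bias": -0.5,
   "truth_table": "0001"
  },
  {
   "weights": [
    0.5,
    0.5
   ],
   "bias": 0.5,
   "truth_table": "1111"
  }
 ]
}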