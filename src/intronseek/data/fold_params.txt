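# Nearest-neighbor parameters for the built-in folding engine (kcal/mol).
# stack <outer pair> <inner pair>: energy of stacking the inner pair directly
# inside the outer pair (pairs written 5'base 3'base).  Loop terms are fixed
# per-loop constants.
stack AU AU -0.9
stack AU UA -1.1
stack AU CG -2.1
stack AU GC -2.2
stack AU GU -0.6
stack AU UG -1.4
stack UA AU -1.3
stack UA UA -0.9
stack UA CG -2.1
stack UA GC -2.4
stack UA GU -1.0
stack UA UG -1.3
stack CG AU -2.1
stack CG UA -2.1
stack CG CG -2.4
stack CG GC -3.3
stack CG GU -1.4
stack CG UG -2.1
stack GC AU -2.4
stack GC UA -2.2
stack GC CG -3.3
stack GC GC -3.4
stack GC GU -1.5
stack GC UG -2.5
stack GU AU -1.3
stack GU UA -1.4
stack GU CG -2.1
stack GU GC -2.5
stack GU GU -0.5
stack GU UG -0.5
stack UG AU -1.0
stack UG UA -0.6
stack UG CG -1.4
stack UG GC -1.5
stack UG GU -0.3
stack UG UG -0.5
hairpin 5.4
internal 3.3
multi 4.6
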