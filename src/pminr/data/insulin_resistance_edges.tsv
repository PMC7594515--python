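# Insulin-resistance pathway topology used by the simulation harness.
# 26 nodes (X1..X26), 37 undirected edges.
# SYNTHETIC STAND-IN: a connected 26-node / 37-edge graph with generic node
# labels that matches the published node and edge counts of the KEGG
# insulin-resistance pathway; the exact published edge set is not
# redistributable here. Simulation results are designed to be robust to the
# particular wiring, so only the size and connectedness of this graph matter.
X1	X2
X2	X3
X3	X4
X4	X5
X4	X10
X5	X6
X6	X7
X7	X8
X8	X9
X9	X10
X10	X11
X11	X12
X12	X13
X13	X14
X14	X15
X15	X16
X16	X17
X17	X18
X18	X19
X19	X20
X20	X21
X21	X22
X22	X23
X23	X24
X24	X25
X25	X26
X2	X5
X3	X7
X6	X10
X8	X12
X11	X14
X13	X17
X15	X19
X16	X20
X18	X22
X21	X25
X5	X9
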