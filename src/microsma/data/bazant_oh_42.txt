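# 42-point unit-sphere quadrature (Bazant-Oh symmetric orbit family).
# 21 hemisphere directions; the loader adds antipodes. Columns: n1 n2 n3 weight.
# Weights sum to 1/2 over the hemisphere; moment-exact through polynomial degree 7.
+1.00000000000000000e+00  +0.00000000000000000e+00  +0.00000000000000000e+00  2.66121681935487589e-02
+0.00000000000000000e+00  +1.00000000000000000e+00  +0.00000000000000000e+00  2.66121681935487589e-02
+0.00000000000000000e+00  +0.00000000000000000e+00  +1.00000000000000000e+00  2.66121681935487589e-02
+7.07106781186547573e-01  +7.07106781186547573e-01  +0.00000000000000000e+00  1.99776689785848630e-02
+7.07106781186547573e-01  -7.07106781186547573e-01  +0.00000000000000000e+00  1.99776689785848630e-02
+7.07106781186547573e-01  +0.00000000000000000e+00  +7.07106781186547573e-01  1.99776689785848630e-02
+7.07106781186547573e-01  +0.00000000000000000e+00  -7.07106781186547573e-01  1.99776689785848630e-02
+0.00000000000000000e+00  +7.07106781186547573e-01  +7.07106781186547573e-01  1.99776689785848630e-02
+0.00000000000000000e+00  +7.07106781186547573e-01  -7.07106781186547573e-01  1.99776689785848630e-02
+8.35882766899760932e-01  +3.88136573901507020e-01  +3.88136573901507020e-01  2.50247901289870449e-02
+8.35882766899760932e-01  +3.88136573901507020e-01  -3.88136573901507020e-01  2.50247901289870449e-02
+8.35882766899760932e-01  -3.88136573901507020e-01  +3.88136573901507020e-01  2.50247901289870449e-02
+8.35882766899760932e-01  -3.88136573901507020e-01  -3.88136573901507020e-01  2.50247901289870449e-02
+3.88136573901507020e-01  +8.35882766899760932e-01  +3.88136573901507020e-01  2.50247901289870449e-02
+3.88136573901507020e-01  +8.35882766899760932e-01  -3.88136573901507020e-01  2.50247901289870449e-02
-3.88136573901507020e-01  +8.35882766899760932e-01  +3.88136573901507020e-01  2.50247901289870449e-02
-3.88136573901507020e-01  +8.35882766899760932e-01  -3.88136573901507020e-01  2.50247901289870449e-02
+3.88136573901507020e-01  +3.88136573901507020e-01  +8.35882766899760932e-01  2.50247901289870449e-02
+3.88136573901507020e-01  -3.88136573901507020e-01  +8.35882766899760932e-01  2.50247901289870449e-02
-3.88136573901507020e-01  +3.88136573901507020e-01  +8.35882766899760932e-01  2.50247901289870449e-02
-3.88136573901507020e-01  -3.88136573901507020e-01  +8.35882766899760932e-01  2.50247901289870449e-02
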