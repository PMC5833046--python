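ABCA1	ABCG1	0.647
ABCA1	ABCG2	0.849
ABCA1	SLC16A1	0.622
ABCA1	SLC16A3	0.865
ABCA1	SLC16A4	0.752
ABCA1	SLC47A1	0.855
ABCG1	ABCG2	0.646
ABCG1	SLC27A4	0.664
ABCG1	SLC47A1	0.862
ABCG2	SLC16A1	0.866
ABCG2	SLC2A1	0.824
ABCG2	SLC47A1	0.628
ABCG2	SLC7A8	0.46
LMBRD1	SLC19A1	0.776
LMBRD1	SLC19A2	0.738
LMBRD1	SLC19A3	0.777
LMBRD1	SLC22A15	0.709
LMBRD1	SLC23A1	0.928
LMBRD1	SLC23A2	0.78
LMBRD1	SLC23A3	0.938
LMBRD1	SLC26A2	0.476
LMBRD1	SLC27A2	0.494
LMBRD1	SLC5A6	0.71
SLC11A2	SLC19A1	0.461
SLC11A2	SLC26A4	0.727
SLC11A2	SLC26A6	0.832
SLC11A2	SLC30A1	0.663
SLC11A2	SLC30A2	0.808
SLC11A2	SLC39A8	0.719
SLC11A2	SLC4A1	0.853
SLC11A2	SLC9A1	0.715
SLC11A2	SLC9B2	0.705
SLC11A2	TRPV6	0.801
SLC12A8	SLC38A2	0.782
SLC12A8	SLC38A5	0.764
SLC12A8	SLC3A2	0.763
SLC12A8	SLC6A2	0.706
SLC12A8	SLC7A1	0.897
SLC12A8	SLC7A11	0.643
SLC12A8	SLC7A5	0.943
SLC12A8	SLC7A6	0.906
SLC12A8	SLC7A7	0.925
SLC12A8	SLC7A8	0.907
SLC16A1	SLC16A3	0.817
SLC16A1	SLC2A1	0.891
SLC16A1	SLC47A1	0.736
SLC16A3	SLC16A4	0.666
SLC16A3	SLC27A4	0.632
SLC16A3	SLC2A1	0.801
SLC16A3	SLC47A1	0.853
SLC16A4	SLC27A2	0.849
SLC16A4	SLC2A1	0.863
SLC16A4	SLC47A1	0.891
SLC16A4	SLC9A1	0.452
SLC19A1	SLC19A2	0.869
SLC19A1	SLC22A15	0.662
SLC19A1	SLC23A2	0.664
SLC19A1	SLC23A3	0.948
SLC19A1	SLC2A1	0.451
SLC19A1	SLC46A1	0.738
SLC19A1	SLC5A6	0.644
SLC19A2	SLC19A3	0.624
SLC19A2	SLC23A2	0.648
SLC19A2	SLC23A3	0.943
SLC19A2	SLC46A1	0.699
SLC19A2	SLC5A6	0.82
SLC19A3	SLC22A15	0.92
SLC19A3	SLC23A1	0.71
SLC19A3	SLC23A2	0.623
SLC19A3	SLC23A3	0.763
SLC19A3	SLC46A1	0.766
SLC19A3	SLC5A6	0.939
SLC22A15	SLC23A1	0.852
SLC22A15	SLC23A3	0.881
SLC23A1	SLC23A2	0.759
SLC23A1	SLC38A2	0.411
SLC23A1	SLC5A6	0.659
SLC23A1	SLC7A11	0.416
SLC23A2	SLC23A3	0.62
SLC23A3	SLC5A6	0.922
SLC26A2	SLC26A4	0.797
SLC26A2	SLC26A6	0.878
SLC26A2	SLC30A4	0.622
SLC26A2	SLC39A1	0.688
SLC26A2	SLC4A1	0.82
SLC26A2	SLC9B2	0.609
SLC26A2	TRPV6	0.819
SLC26A4	SLC26A6	0.733
SLC26A4	SLC30A1	0.75
SLC26A4	SLC30A2	0.811
SLC26A4	SLC39A1	0.709
SLC26A4	SLC5A5	0.669
SLC26A4	SLC9A1	0.675
SLC26A4	SLC9B2	0.863
SLC26A6	SLC30A2	0.739
SLC26A6	SLC30A4	0.867
SLC26A6	SLC39A1	0.666
SLC26A6	SLC9A1	0.78
SLC26A6	SLC9B2	0.76
SLC27A2	SLC27A4	0.694
SLC27A2	SLC2A1	0.648
SLC27A2	SLC47A1	0.917
SLC27A2	SLC4A1	0.475
SLC27A4	SLC2A1	0.707
SLC27A4	SLC47A1	0.747
SLC2A1	SLC47A1	0.896
SLC30A1	SLC30A2	0.864
SLC30A1	SLC39A1	0.719
SLC30A1	SLC39A8	0.933
SLC30A1	SLC4A1	0.782
SLC30A1	SLC5A5	0.923
SLC30A1	SLC9A1	0.749
SLC30A1	TRPV6	0.943
SLC30A2	SLC30A4	0.884
SLC30A2	SLC39A1	0.882
SLC30A2	SLC9A1	0.618
SLC30A2	SLC9B2	0.92
SLC30A4	SLC39A1	0.648
SLC30A4	SLC39A8	0.936
SLC30A4	SLC5A5	0.92
SLC30A4	TRPV6	0.82
SLC38A1	SLC38A2	0.887
SLC38A1	SLC38A5	0.783
SLC38A1	SLC3A2	0.656
SLC38A1	SLC6A2	0.807
SLC38A1	SLC7A1	0.891
SLC38A1	SLC7A11	0.602
SLC38A1	SLC7A5	0.736
SLC38A1	SLC7A6	0.741
SLC38A2	SLC38A5	0.879
SLC38A2	SLC47A1	0.47
SLC38A2	SLC7A1	0.694
SLC38A2	SLC7A5	0.653
SLC38A2	SLC7A6	0.939
SLC38A2	SLC7A8	0.732
SLC38A5	SLC3A2	0.612
SLC38A5	SLC6A2	0.927
SLC38A5	SLC7A11	0.73
SLC38A5	SLC7A6	0.835
SLC38A5	SLC7A7	0.651
SLC38A5	SLC7A8	0.684
SLC39A1	SLC39A8	0.747
SLC39A1	SLC4A1	0.611
SLC39A1	SLC9A1	0.614
SLC39A1	SLC9B2	0.658
SLC39A8	SLC9A1	0.801
SLC39A8	SLC9B2	0.881
SLC39A8	TRPV6	0.885
SLC3A2	SLC6A2	0.697
SLC3A2	SLC7A1	0.819
SLC3A2	SLC7A5	0.777
SLC3A2	SLC7A6	0.948
SLC3A2	SLC9A1	0.485
SLC46A1	SLC5A6	0.611
SLC4A1	SLC7A5	0.447
SLC4A1	SLC9A1	0.831
SLC4A1	TRPV6	0.605
SLC5A5	SLC9A1	0.73
SLC5A5	SLC9B2	0.679
SLC5A5	TRPV6	0.868
SLC6A2	SLC7A5	0.812
SLC6A2	SLC7A7	0.663
SLC6A2	SLC7A8	0.792
SLC7A1	SLC7A11	0.729
SLC7A1	SLC7A5	0.914
SLC7A1	SLC7A6	0.774
SLC7A1	SLC7A7	0.604
SLC7A1	SLC7A8	0.842
SLC7A11	SLC7A5	0.809
SLC7A11	SLC7A6	0.754
SLC7A11	SLC7A8	0.906
SLC7A5	SLC7A6	0.871
SLC7A5	SLC7A7	0.789
SLC7A5	SLC7A8	0.905
SLC7A6	SLC7A7	0.679
SLC7A7	SLC7A8	0.705
SLC9A1	SLC9B2	0.854
SLC9A1	TRPV6	0.902
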