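estimator,criterion,n_endog,n_excl,critical_value
TSLS,size10,1,1,16.38
TSLS,size10,1,2,19.93
TSLS,size10,1,3,22.3
TSLS,size10,1,4,24.58
TSLS,size10,1,5,26.87
TSLS,size10,1,6,29.18
TSLS,size10,1,7,31.5
TSLS,size10,1,8,33.84
TSLS,size10,1,9,36.19
TSLS,size10,1,10,38.54
TSLS,size15,1,1,8.96
TSLS,size15,1,2,11.59
TSLS,size15,1,3,12.83
TSLS,size15,1,4,13.96
TSLS,size15,1,5,15.09
TSLS,size15,1,6,16.23
TSLS,size15,1,7,17.38
TSLS,size15,1,8,18.54
TSLS,size15,1,9,19.71
TSLS,size15,1,10,20.88
TSLS,size20,1,1,6.66
TSLS,size20,1,2,8.75
TSLS,size20,1,3,9.54
TSLS,size20,1,4,10.26
TSLS,size20,1,5,10.98
TSLS,size20,1,6,11.72
TSLS,size20,1,7,12.48
TSLS,size20,1,8,13.24
TSLS,size20,1,9,14.01
TSLS,size20,1,10,14.78
TSLS,size25,1,1,5.53
TSLS,size25,1,2,7.25
TSLS,size25,1,3,7.8
TSLS,size25,1,4,8.31
TSLS,size25,1,5,8.84
TSLS,size25,1,6,9.38
TSLS,size25,1,7,9.93
TSLS,size25,1,8,10.5
TSLS,size25,1,9,11.07
TSLS,size25,1,10,11.65
LIML,size10,1,1,16.38
LIML,size10,1,2,8.68
LIML,size10,1,3,6.46
LIML,size10,1,4,5.44
LIML,size10,1,5,4.84
LIML,size10,1,6,4.45
LIML,size10,1,7,4.18
LIML,size10,1,8,3.97
LIML,size10,1,9,3.81
LIML,size10,1,10,3.68
LIML,size15,1,1,8.96
LIML,size15,1,2,5.33
LIML,size15,1,3,4.36
LIML,size15,1,4,3.87
LIML,size15,1,5,3.56
LIML,size15,1,6,3.34
LIML,size15,1,7,3.18
LIML,size15,1,8,3.04
LIML,size15,1,9,2.93
LIML,size15,1,10,2.84
LIML,size20,1,1,6.66
LIML,size20,1,2,4.42
LIML,size20,1,3,3.69
LIML,size20,1,4,3.3
LIML,size20,1,5,3.05
LIML,size20,1,6,2.87
LIML,size20,1,7,2.73
LIML,size20,1,8,2.63
LIML,size20,1,9,2.54
LIML,size20,1,10,2.46
LIML,size25,1,1,5.53
LIML,size25,1,2,3.92
LIML,size25,1,3,3.32
LIML,size25,1,4,2.98
LIML,size25,1,5,2.76
LIML,size25,1,6,2.61
LIML,size25,1,7,2.49
LIML,size25,1,8,2.39
LIML,size25,1,9,2.32
LIML,size25,1,10,2.25
TSLS,bias5,1,3,13.91
TSLS,bias5,1,4,16.85
TSLS,bias5,1,5,18.37
TSLS,bias5,1,6,19.28
TSLS,bias5,1,7,19.86
TSLS,bias5,1,8,20.25
TSLS,bias5,1,9,20.53
TSLS,bias5,1,10,20.74
TSLS,bias10,1,3,9.08
TSLS,bias10,1,4,10.27
TSLS,bias10,1,5,10.83
TSLS,bias10,1,6,11.12
TSLS,bias10,1,7,11.29
TSLS,bias10,1,8,11.39
TSLS,bias10,1,9,11.46
TSLS,bias10,1,10,11.49
TSLS,bias20,1,3,6.46
TSLS,bias20,1,4,6.71
TSLS,bias20,1,5,6.77
TSLS,bias20,1,6,6.76
TSLS,bias20,1,7,6.73
TSLS,bias20,1,8,6.69
TSLS,bias20,1,9,6.65
TSLS,bias20,1,10,6.61
TSLS,bias30,1,3,5.39
TSLS,bias30,1,4,5.34
TSLS,bias30,1,5,5.25
TSLS,bias30,1,6,5.15
TSLS,bias30,1,7,5.07
TSLS,bias30,1,8,4.99
TSLS,bias30,1,9,4.92
TSLS,bias30,1,10,4.86
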