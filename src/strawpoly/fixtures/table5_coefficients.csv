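term,response,beta,stars
intercept,hydroxybenzoic,157.15,**
X1,hydroxybenzoic,-279.32,
X2,hydroxybenzoic,472.95,***
X3,hydroxybenzoic,-175.01,**
X4,hydroxybenzoic,-281.58,*
X5,hydroxybenzoic,-288.93,*
X1^2,hydroxybenzoic,-103.11,
X2^2,hydroxybenzoic,830.57,***
X4^2,hydroxybenzoic,-169.99,
X5^2,hydroxybenzoic,375.45,***
X1X2,hydroxybenzoic,-1070.49,***
X1X3,hydroxybenzoic,-392.48,***
X1X4,hydroxybenzoic,-313.79,*
X1X5,hydroxybenzoic,44.96,
X2X3,hydroxybenzoic,224.98,**
X2X4,hydroxybenzoic,236.49,
X2X5,hydroxybenzoic,-443.79,***
X3X4,hydroxybenzoic,-103.02,
X3X5,hydroxybenzoic,217.70,***
X4X5,hydroxybenzoic,101.01,
R2,hydroxybenzoic,0.949,
R2_adj,hydroxybenzoic,0.922,
RMSE,hydroxybenzoic,7.455,
intercept,hydroxycinnamic,57.81,
X1,hydroxycinnamic,1463.86,
X2,hydroxycinnamic,-1147.95,
X3,hydroxycinnamic,460.15,
X4,hydroxycinnamic,-678.45,
X5,hydroxycinnamic,-1549.26,**
X1^2,hydroxycinnamic,-5.56,
X2^2,hydroxycinnamic,-160.05,
X4^2,hydroxycinnamic,-196.20,
X5^2,hydroxycinnamic,1625.61,***
X1X2,hydroxycinnamic,-488.82,
X1X3,hydroxycinnamic,-1681.32,***
X1X4,hydroxycinnamic,1316.06,
X1X5,hydroxycinnamic,543.74,
X2X3,hydroxycinnamic,1310.92,***
X2X4,hydroxycinnamic,-1483.73,*
X2X5,hydroxycinnamic,-2028.47,***
X3X4,hydroxycinnamic,274.62,
X3X5,hydroxycinnamic,593.82,*
X4X5,hydroxycinnamic,-486.24,
R2,hydroxycinnamic,0.810,
R2_adj,hydroxycinnamic,0.710,
RMSE,hydroxycinnamic,38.418,
intercept,flavones,214.59,***
X1,flavones,100.54,
X2,flavones,27.59,
X3,flavones,-59.15,
X4,flavones,-64.99,
X5,flavones,-74.35,
X1^2,flavones,-158.66,
X2^2,flavones,-190.47,
X4^2,flavones,21.38,
X5^2,flavones,316.39,***
X1X2,flavones,-249.28,
X1X3,flavones,-109.58,
X1X4,flavones,116.41,
X1X5,flavones,277.76,***
X2X3,flavones,27.71,
X2X4,flavones,-141.22,
X2X5,flavones,-346.02,*
X3X4,flavones,24.52,
X3X5,flavones,167.65,*
X4X5,flavones,7.49,
R2,flavones,0.857,
R2_adj,flavones,0.781,
RMSE,flavones,8.948,
intercept,abts,2.78,***
X1,abts,5.57,
X2,abts,-10.31,*
X3,abts,1.49,
X4,abts,1.90,
X5,abts,0.02,
X1^2,abts,-4.16,*
X2^2,abts,-15.60,*
X4^2,abts,0.37,
X5^2,abts,0.07,
X1X2,abts,14.78,*
X1X3,abts,0.77,
X1X4,abts,-0.80,
X1X5,abts,5.15,**
X2X3,abts,-2.11,**
X2X4,abts,1.49,
X2X5,abts,-4.53,
X3X4,abts,1.84,
X3X5,abts,-0.38,
X4X5,abts,-1.42,
R2,abts,0.99,
R2_adj,abts,0.84,
RMSE,abts,0.04,
intercept,dpph,0.57,
X1,dpph,-11.86,
X2,dpph,10.23,
X3,dpph,-4.46,
X4,dpph,1.94,
X5,dpph,6.15,
X1^2,dpph,6.25,
X2^2,dpph,21.44,
X4^2,dpph,8.80,
X5^2,dpph,-2.74,
X1X2,dpph,-18.51,
X1X3,dpph,0.39,
X1X4,dpph,-3.40,
X1X5,dpph,-4.00,
X2X3,dpph,-1.94,
X2X4,dpph,0.44,
X2X5,dpph,5.55,
X3X4,dpph,-5.49,
X3X5,dpph,-4.47,
X4X5,dpph,5.48,
R2,dpph,0.92,
R2_adj,dpph,0.84,
RMSE,dpph,0.12,
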